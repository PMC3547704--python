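"""End-to-end pipeline: data -> normalization -> trees -> biclusters -> robust groups.

One declarative :class:`PipelineConfig` (YAML round-trippable) drives the
whole analysis; :func:`run_pipeline` writes every artifact — the analysis
matrix, gene/condition dendrograms with cophenetic coefficients, the
mean-matrix biclusters, the bootstrap ensemble and the robust groups with
their bipartite export — into an output directory together with a config
echo, deterministically for a given master seed.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from .bicluster import BiclusterConfig
from .expression import (
    ExpressionMatrix,
    ReplicatedExpression,
    analysis_matrix,
    load_replicates_long,
    write_wide_matrix,
)
from .hierarchy import agglomerate, cophenetic_correlation, pairwise_distances
from .model import RobustBiclustering, SequentialBiclustering
from .synthetic import SyntheticSpec, endoderm_benchmark_spec, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative description of one full analysis run."""

    input_path: str | None = None  # long-format replicate TSV; None -> synthetic
    synthetic: SyntheticSpec | None = None  # None with no input -> benchmark spec
    log2: bool = True
    normalize: bool = False  # z-scoring applies to the trees regardless
    distance_metric: str = "euclidean"
    linkage: str = "average"
    bicluster: BiclusterConfig = field(default_factory=BiclusterConfig)
    n_mean_biclusters: int = 5
    n_datasets: int = 1000
    runs_per_dataset: int = 5
    threshold_fraction: float = 0.5
    max_genes: int = 3
    max_conditions: int = 7
    outdir: str = "sebic_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if self.runs_per_dataset < 1:
            raise ValueError("runs_per_dataset must be >= 1")
        if not (0.0 < self.threshold_fraction <= 1.0):
            raise ValueError("threshold_fraction must be in (0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("bicluster") is not None and not isinstance(d["bicluster"], BiclusterConfig):
            d["bicluster"] = BiclusterConfig(**d["bicluster"])
        if d.get("synthetic") is not None and not isinstance(d["synthetic"], SyntheticSpec):
            sd = dict(d["synthetic"])
            if sd.get("implants"):
                from .synthetic import ImplantSpec

                sd["implants"] = tuple(
                    ImplantSpec(**{k: tuple(v) if isinstance(v, list) else v for k, v in imp.items()})
                    for imp in sd["implants"]
                )
            for key in ("gene_ids", "condition_ids"):
                if sd.get(key) is not None:
                    sd[key] = tuple(sd[key])
            d["synthetic"] = SyntheticSpec(**sd)
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text))


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full workflow; returns a manifest of written artifacts.

    Rerunning with the same config and seed reproduces every output
    byte-for-byte (all randomness derives from ``cfg.seed``).
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest: dict = {"outdir": cfg.outdir}

    def path(name: str) -> str:
        return os.path.join(cfg.outdir, name)

    with open(path("config.yaml"), "w") as fh:
        fh.write(cfg.to_yaml())
    manifest["config"] = path("config.yaml")

    # --- data ---------------------------------------------------------
    @_stage("data")
    def load_data() -> ReplicatedExpression:
        if cfg.input_path is not None:
            return load_replicates_long(cfg.input_path)
        spec = cfg.synthetic or endoderm_benchmark_spec(seed=cfg.seed)
        data, truth = generate_dataset(spec)
        with open(path("ground_truth.json"), "w") as fh:
            fh.write(truth.to_json())
        manifest["ground_truth"] = path("ground_truth.json")
        return data

    data = load_data()

    # --- analysis matrices -------------------------------------------
    # trees use the row z-scored matrix; bicluster stages the log2 matrix
    @_stage("normalize")
    def make_matrices() -> tuple[ExpressionMatrix, ExpressionMatrix]:
        x_tree = analysis_matrix(data, log2=cfg.log2, normalize=True)
        x_bic = analysis_matrix(data, log2=cfg.log2, normalize=cfg.normalize)
        write_wide_matrix(x_tree, path("normalized_matrix.tsv"))
        write_wide_matrix(x_bic, path("analysis_matrix.tsv"))
        manifest["normalized_matrix"] = path("normalized_matrix.tsv")
        manifest["analysis_matrix"] = path("analysis_matrix.tsv")
        return x_tree, x_bic

    x_tree, x_bic = make_matrices()

    # --- hierarchical clustering -------------------------------------
    @_stage("hierarchical")
    def run_trees() -> dict:
        report = {}
        for axis in ("genes", "conditions"):
            d = pairwise_distances(x_tree, axis=axis, metric=cfg.distance_metric)
            labels = x_tree.gene_ids if axis == "genes" else x_tree.condition_ids
            tree = agglomerate(d, linkage=cfg.linkage, labels=labels)
            newick = tree.to_newick()
            with open(path(f"tree_{axis}.nwk"), "w") as fh:
                fh.write(newick + "\n")
            manifest[f"tree_{axis}"] = path(f"tree_{axis}.nwk")
            report[axis] = {
                "cophenetic_correlation": cophenetic_correlation(tree, d),
                "metric": cfg.distance_metric,
                "linkage": cfg.linkage,
            }
        with open(path("hierarchical.json"), "w") as fh:
            json.dump(report, fh, sort_keys=True, indent=2)
        manifest["hierarchical"] = path("hierarchical.json")
        return report

    manifest["cophenetic"] = run_trees()

    # --- mean-matrix biclustering ------------------------------------
    @_stage("bicluster")
    def run_mean_biclusters():
        model = SequentialBiclustering(x_bic, cfg.bicluster)
        res = model.fit(n_biclusters=cfg.n_mean_biclusters, seed=cfg.seed)
        with open(path("mean_biclusters.json"), "w") as fh:
            fh.write(res.to_json())
        manifest["mean_biclusters"] = path("mean_biclusters.json")
        return res

    mean_res = run_mean_biclusters()
    manifest["n_mean_biclusters"] = mean_res.n_found

    # --- bootstrap robust mining -------------------------------------
    @_stage("robust")
    def run_robust():
        model = RobustBiclustering(
            data,
            cfg.bicluster,
            n_datasets=cfg.n_datasets,
            runs_per_dataset=cfg.runs_per_dataset,
            threshold_fraction=cfg.threshold_fraction,
            max_genes=cfg.max_genes,
            max_conditions=cfg.max_conditions,
            log2=cfg.log2,
            normalize=cfg.normalize,
        )
        res = model.fit(seed=cfg.seed)
        res.ensemble.to_jsonl(path("ensemble.jsonl"))
        with open(path("robust_groups.json"), "w") as fh:
            fh.write(res.to_json())
        with open(path("robust_groups.tsv"), "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["group_id", "genes", "conditions", "support"])
            for gid, grp in enumerate(res.groups, start=1):
                w.writerow(
                    [gid, "+".join(sorted(grp.genes)), ";".join(sorted(grp.conditions)), f"{grp.support:.6f}"]
                )
        with open(path("bipartite_edges.tsv"), "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["gene", "condition", "group_id", "support"])
            for gene, condition, gid, support in res.to_bipartite():
                w.writerow([gene, condition, gid, f"{support:.6f}"])
        manifest["ensemble"] = path("ensemble.jsonl")
        manifest["robust_groups"] = path("robust_groups.json")
        manifest["bipartite_edges"] = path("bipartite_edges.tsv")
        return res

    robust_res = run_robust()
    manifest["n_robust_groups"] = len(robust_res.groups)

    with open(path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
    return manifest
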