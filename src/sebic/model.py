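"""Model/Results interface over the biclustering machinery.

Two estimator-style entry points, in the spirit of statsmodels:

``SequentialBiclustering``
    built from a (normalized) expression matrix; ``fit`` runs the
    sequential evolutionary search and returns results carrying the
    biclusters, their quality metrics and a ``summary()`` table.

``RobustBiclustering``
    built from the replicated fold-change tensor; ``fit`` runs the full
    bootstrap ensemble and pattern mining and returns results carrying the
    robust patterns, groups and the bipartite export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bicluster import (
    Bicluster,
    BiclusterConfig,
    CoverageMatrix,
    mean_squared_residue,
    row_variance,
    sequential_extract,
)
from .expression import ExpressionMatrix, ReplicatedExpression, analysis_matrix
from .robust import (
    BootstrapEnsemble,
    RobustGroup,
    SubsetPattern,
    bipartite_graph,
    count_patterns,
    group_patterns,
    robust_patterns,
    run_ensemble,
    to_bipartite,
)

__all__ = [
    "SequentialBiclustering",
    "SequentialBiclusteringResults",
    "RobustBiclustering",
    "RobustBiclusteringResults",
]


class SequentialBiclustering:
    """Sequential evolutionary bicluster search on an expression matrix.

    Parameters
    ----------
    x : ExpressionMatrix
        The matrix to analyse; typically row-normalized log2 fold changes.
    config : BiclusterConfig, optional
        Scoring (delta, Wr, Wc, penalty form) and GA parameters.

    Examples
    --------
    >>> model = SequentialBiclustering(x)
    >>> res = model.fit(n_biclusters=5, seed=0)
    >>> print(res.summary())
    """

    def __init__(self, x: ExpressionMatrix, config: BiclusterConfig | None = None) -> None:
        self.x = x
        self.config = config or BiclusterConfig()

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, config: BiclusterConfig | None = None, **kwargs
    ) -> "SequentialBiclustering":
        return cls(ExpressionMatrix.from_frame(frame, **kwargs), config)

    @classmethod
    def from_replicates(
        cls,
        data: ReplicatedExpression,
        config: BiclusterConfig | None = None,
        *,
        log2: bool = True,
        normalize: bool = False,
    ) -> "SequentialBiclustering":
        return cls(analysis_matrix(data, log2=log2, normalize=normalize), config)

    def fit(self, n_biclusters: int = 5, seed: int = 0) -> "SequentialBiclusteringResults":
        cov = CoverageMatrix(self.x.n_genes, self.x.n_conditions)
        biclusters = sequential_extract(
            self.x, cfg=self.config, k=n_biclusters, seed=seed, cov=cov
        )
        return SequentialBiclusteringResults(
            model=self, biclusters=tuple(biclusters), coverage=cov, seed=seed
        )


@dataclass(frozen=True)
class SequentialBiclusteringResults:
    """Biclusters found by :class:`SequentialBiclustering.fit`."""

    model: SequentialBiclustering
    biclusters: tuple[Bicluster, ...]
    coverage: CoverageMatrix
    seed: int

    @property
    def n_found(self) -> int:
        return len(self.biclusters)

    def metrics(self) -> pd.DataFrame:
        """Per-bicluster quality table (sizes, MSR, row variance)."""
        x = self.model.x
        rows = []
        for k, b in enumerate(self.biclusters, start=1):
            rows.append(
                {
                    "bicluster": k,
                    "n_genes": b.n_rows,
                    "n_conditions": b.n_cols,
                    "msr": mean_squared_residue(b, x),
                    "row_variance": row_variance(b, x),
                    "genes": ",".join(b.gene_labels(x)),
                    "conditions": ",".join(b.condition_labels(x)),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Sequential evolutionary biclustering",
            "=" * 68,
            f"matrix: {self.model.x.n_genes} genes x {self.model.x.n_conditions} conditions"
            f" (normalized={self.model.x.normalized}, log2={self.model.x.log2})",
            f"delta={cfg.delta}  Wr={cfg.w_r}  Wc={cfg.w_c}  penalty={cfg.penalty_form}"
            f"  seed={self.seed}",
            f"biclusters found: {self.n_found}",
            "-" * 68,
        ]
        if self.n_found:
            table = self.metrics()
            with pd.option_context("display.width", 120, "display.max_colwidth", 40):
                lines.append(
                    table[["bicluster", "n_genes", "n_conditions", "msr", "row_variance"]]
                    .round(4)
                    .to_string(index=False)
                )
            for _, row in table.iterrows():
                lines.append(f"  [{int(row['bicluster'])}] genes: {row['genes']}")
                lines.append(f"      conditions: {row['conditions']}")
        return "\n".join(lines)

    def to_json(self) -> str:
        x = self.model.x
        payload = {
            "config": self.model.config.to_dict(),
            "seed": self.seed,
            "biclusters": [b.to_dict(x) for b in self.biclusters],
        }
        return json.dumps(payload, sort_keys=True, indent=2)


class RobustBiclustering:
    """Bootstrap-ensemble biclustering with robust sub-pattern mining.

    Parameters
    ----------
    data : ReplicatedExpression
        Fold-change tensor genes x conditions x replicates.
    config : BiclusterConfig, optional
    n_datasets : int
        Number of bootstrap pseudo-datasets (field default 1000).
    runs_per_dataset : int
        Sequential biclusters extracted per pseudo-dataset (default 5).
    threshold_fraction : float
        Minimum support for a pattern to be robust (default 0.5).
    """

    def __init__(
        self,
        data: ReplicatedExpression,
        config: BiclusterConfig | None = None,
        *,
        n_datasets: int = 1000,
        runs_per_dataset: int = 5,
        threshold_fraction: float = 0.5,
        max_genes: int = 3,
        max_conditions: int = 7,
        log2: bool = True,
        normalize: bool = False,
    ) -> None:
        if n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if not (0.0 < threshold_fraction <= 1.0):
            raise ValueError("threshold_fraction must be in (0, 1]")
        self.data = data
        self.config = config or BiclusterConfig()
        self.n_datasets = n_datasets
        self.runs_per_dataset = runs_per_dataset
        self.threshold_fraction = threshold_fraction
        self.max_genes = max_genes
        self.max_conditions = max_conditions
        self.log2 = log2
        self.normalize = normalize

    def fit(self, seed: int = 0) -> "RobustBiclusteringResults":
        ensemble = run_ensemble(
            self.data,
            cfg=self.config,
            n_datasets=self.n_datasets,
            runs_per_dataset=self.runs_per_dataset,
            seed=seed,
            log2=self.log2,
            normalize=self.normalize,
        )
        patterns = count_patterns(
            ensemble, max_genes=self.max_genes, max_conditions=self.max_conditions
        )
        robust = robust_patterns(patterns, ensemble.n_datasets, self.threshold_fraction)
        groups = group_patterns(robust)
        return RobustBiclusteringResults(
            model=self,
            ensemble=ensemble,
            patterns=tuple(patterns),
            robust=tuple(robust),
            groups=tuple(groups),
            seed=seed,
        )


@dataclass(frozen=True)
class RobustBiclusteringResults:
    """Robust patterns and groups from :class:`RobustBiclustering.fit`."""

    model: RobustBiclustering
    ensemble: BootstrapEnsemble
    patterns: tuple[SubsetPattern, ...]
    robust: tuple[SubsetPattern, ...]
    groups: tuple[RobustGroup, ...]
    seed: int

    def pattern_table(self, top: int | None = 20) -> pd.DataFrame:
        rows = [
            {
                "genes": "+".join(sorted(p.genes)),
                "conditions": ";".join(sorted(p.conditions)),
                "frequency": p.frequency,
                "support": p.support,
            }
            for p in (self.patterns[:top] if top else self.patterns)
        ]
        return pd.DataFrame(rows)

    def to_bipartite(self) -> list[tuple[str, str, int, float]]:
        return to_bipartite(list(self.groups))

    def bipartite_graph(self):
        return bipartite_graph(list(self.groups))

    def summary(self) -> str:
        m = self.model
        lines = [
            "Robust biclustering (bootstrap ensemble)",
            "=" * 68,
            f"data: {m.data.n_genes} genes x {m.data.n_conditions} conditions, "
            f"replicates per cell {int(m.data.replicate_counts.min())}"
            f"-{int(m.data.replicate_counts.max())}",
            f"pseudo-datasets: {self.ensemble.n_datasets}  runs/dataset: {m.runs_per_dataset}"
            f"  threshold: {m.threshold_fraction:.0%}  seed: {self.seed}",
            f"patterns enumerated: {len(self.patterns)}  robust (maximal): {len(self.robust)}"
            f"  groups: {len(self.groups)}",
            "-" * 68,
        ]
        for gid, group in enumerate(self.groups, start=1):
            lines.append(
                f"Group {gid}: ({', '.join(sorted(group.genes))} | "
                f"{', '.join(sorted(group.conditions))})  support={group.support:.2f}"
            )
            for p in group.members:
                lines.append(
                    f"    {p.frequency}/{p.n_datasets}  conditions: "
                    f"{', '.join(sorted(p.conditions))}"
                )
        if not self.groups:
            lines.append("no pattern reached the support threshold")
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "n_datasets": self.ensemble.n_datasets,
            "threshold_fraction": self.model.threshold_fraction,
            "robust_patterns": [p.to_dict() for p in self.robust],
            "groups": [g.to_dict() for g in self.groups],
        }
        return json.dumps(payload, sort_keys=True, indent=2)
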