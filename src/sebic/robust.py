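"""Bootstrap ensemble biclustering and robust sub-pattern mining.

Biological replicates of a small expression screen carry substantial
noise, so a bicluster found on the mean matrix may not survive an
experimental repeat.  Bootstrapping emulates repeats: each pseudo-dataset
resamples every cell's replicates with replacement, averages them, and is
re-analysed by the full sequential bicluster search.  Whole biclusters
rarely recur verbatim across pseudo-datasets; instead, small gene-set x
condition-set *sub-patterns* of the biclusters recur, and those contained
in some bicluster of at least a threshold fraction (default 50%) of the
pseudo-datasets are called robust.  Robust patterns sharing an identical
gene set merge into groups, reported as a bipartite gene-condition graph.
"""

from __future__ import annotations

import itertools
import json
import logging
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .bicluster import BiclusterConfig, sequential_extract
from .expression import ExpressionMatrix, ReplicatedExpression, log2_matrix, normalize_rows

__all__ = [
    "BootstrapEnsemble",
    "SubsetPattern",
    "RobustGroup",
    "bootstrap_matrix",
    "run_ensemble",
    "count_patterns",
    "robust_patterns",
    "group_patterns",
    "to_bipartite",
    "bipartite_graph",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubsetPattern:
    """A (gene-set, condition-set) sub-pattern with its bootstrap support."""

    genes: frozenset[str]
    conditions: frozenset[str]
    frequency: int
    n_datasets: int

    @property
    def support(self) -> float:
        return self.frequency / self.n_datasets

    def contains(self, other: "SubsetPattern") -> bool:
        return other.genes <= self.genes and other.conditions <= self.conditions

    def to_dict(self) -> dict:
        return {
            "genes": sorted(self.genes),
            "conditions": sorted(self.conditions),
            "frequency": self.frequency,
            "support": self.support,
        }


@dataclass(frozen=True)
class RobustGroup:
    """Robust patterns sharing one gene set; conditions are their union."""

    genes: frozenset[str]
    conditions: frozenset[str]
    members: tuple[SubsetPattern, ...]

    @property
    def support(self) -> float:
        return max(p.support for p in self.members)

    def to_dict(self) -> dict:
        return {
            "genes": sorted(self.genes),
            "conditions": sorted(self.conditions),
            "support": self.support,
            "members": [p.to_dict() for p in self.members],
        }


@dataclass(frozen=True)
class BootstrapEnsemble:
    """Sequentially extracted biclusters of every pseudo-dataset.

    ``biclusters[d]`` is the (possibly empty) list of label-space
    biclusters of pseudo-dataset d.  Label space (not index space) so that
    patterns are comparable across datasets regardless of ordering.
    """

    gene_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]
    biclusters: tuple[tuple[tuple[frozenset[str], frozenset[str]], ...], ...]
    master_seed: int | None = None

    @property
    def n_datasets(self) -> int:
        return len(self.biclusters)

    def to_jsonl(self, path: str) -> None:
        with open(path, "w") as fh:
            for per_dataset in self.biclusters:
                line = [
                    {"genes": sorted(g), "conditions": sorted(c)} for g, c in per_dataset
                ]
                fh.write(json.dumps(line, sort_keys=True) + "\n")

    @classmethod
    def from_jsonl(
        cls, path: str, gene_ids: tuple[str, ...], condition_ids: tuple[str, ...]
    ) -> "BootstrapEnsemble":
        rows = []
        with open(path) as fh:
            for line in fh:
                entries = json.loads(line)
                rows.append(
                    tuple(
                        (frozenset(e["genes"]), frozenset(e["conditions"])) for e in entries
                    )
                )
        return cls(gene_ids, condition_ids, tuple(rows))


# ---------------------------------------------------------------------------
# Bootstrap resampling
# ---------------------------------------------------------------------------


def bootstrap_matrix(
    data: ReplicatedExpression,
    seed: int | np.random.SeedSequence | np.random.Generator | None = 0,
    *,
    log2: bool = True,
    normalize: bool = False,
    max_retries: int = 10,
) -> ExpressionMatrix:
    """One pseudo-dataset: per-cell resampling with replacement, then mean.

    Each cell draws as many replicates as it actually has, with
    replacement, and is replaced by their mean; the matrix is then put on
    the analysis scale (log2, row z-score).  A resampled constant row —
    possible only in degenerate data — triggers a logged redraw, bounded
    by ``max_retries``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = data.values
    n, m, rmax = v.shape
    counts = data.replicate_counts
    last_error: Exception | None = None
    for attempt in range(max_retries):
        # draw a replicate index per (cell, slot), valid within each cell's count
        draws = rng.integers(0, counts[:, :, None], size=(n, m, rmax), endpoint=False)
        sampled = np.take_along_axis(v, draws, axis=2)
        slot = np.arange(rmax)[None, None, :]
        sampled = np.where(slot < counts[:, :, None], sampled, np.nan)
        with np.errstate(invalid="ignore"):
            means = np.nanmean(sampled, axis=2)
        x = ExpressionMatrix(data.gene_ids, data.condition_ids, means)
        try:
            if log2:
                x = log2_matrix(x)
            if normalize:
                x = normalize_rows(x)
            return x
        except ValueError as exc:
            last_error = exc
            logger.warning("degenerate bootstrap draw (attempt %d): %s", attempt + 1, exc)
    raise ValueError(f"bootstrap failed after {max_retries} redraws: {last_error}")


def run_ensemble(
    data: ReplicatedExpression,
    cfg: BiclusterConfig | None = None,
    n_datasets: int = 1000,
    runs_per_dataset: int = 5,
    seed: int = 0,
    *,
    log2: bool = True,
    normalize: bool = False,
) -> BootstrapEnsemble:
    """Bootstrap + sequential biclustering over ``n_datasets`` pseudo-datasets.

    The master seed spawns an independent (bootstrap, search) seed pair per
    dataset, so the ensemble is reproducible and trivially parallelizable.
    A dataset whose bootstrap or search fails is logged and recorded as an
    empty list; the ensemble never aborts.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    if runs_per_dataset < 1:
        raise ValueError("runs_per_dataset must be >= 1")
    cfg = cfg or BiclusterConfig()
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_datasets)
    results = []
    for d in range(n_datasets):
        boot_ss, ga_ss = children[d].spawn(2)
        try:
            x = bootstrap_matrix(data, boot_ss, log2=log2, normalize=normalize)
            found = sequential_extract(x, cfg=cfg, k=runs_per_dataset, seed=ga_ss)
            results.append(
                tuple(
                    (frozenset(b.gene_labels(x)), frozenset(b.condition_labels(x)))
                    for b in found
                )
            )
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("pseudo-dataset %d failed: %s", d, exc)
            results.append(())
    return BootstrapEnsemble(data.gene_ids, data.condition_ids, tuple(results), master_seed=seed)


# ---------------------------------------------------------------------------
# Pattern mining
# ---------------------------------------------------------------------------


def _subpatterns(
    genes: frozenset[str],
    conditions: frozenset[str],
    min_genes: int,
    max_genes: int,
    min_conditions: int,
    max_conditions: int,
):
    gs = sorted(genes)
    cs = sorted(conditions)
    for ng in range(min_genes, min(max_genes, len(gs)) + 1):
        for gsub in itertools.combinations(gs, ng):
            for nc in range(min_conditions, min(max_conditions, len(cs)) + 1):
                for csub in itertools.combinations(cs, nc):
                    yield frozenset(gsub), frozenset(csub)


def count_patterns(
    ens: BootstrapEnsemble,
    max_genes: int = 3,
    max_conditions: int = 7,
    min_genes: int = 2,
    min_conditions: int = 2,
) -> list[SubsetPattern]:
    """Count each sub-pattern once per pseudo-dataset that contains it.

    A pattern (G, C) is contained in a dataset when G is a subset of the
    gene set and C of the condition set of *any* of that dataset's
    biclusters; multiplicity within a dataset does not matter, so no
    frequency can exceed the number of datasets (and containment is
    anti-monotone: sub-patterns are at least as frequent).
    """
    if ens.n_datasets == 0:
        raise ValueError("empty ensemble")
    if min_genes < 2 or min_conditions < 2:
        raise ValueError("pattern size limits must be >= 2")
    if max_genes < min_genes or max_conditions < min_conditions:
        raise ValueError("max size limits below min size limits")
    counter: Counter = Counter()
    for per_dataset in ens.biclusters:
        seen: set = set()
        for genes, conditions in per_dataset:
            seen.update(
                _subpatterns(genes, conditions, min_genes, max_genes, min_conditions, max_conditions)
            )
        counter.update(seen)
    patterns = [
        SubsetPattern(g, c, freq, ens.n_datasets) for (g, c), freq in counter.items()
    ]
    patterns.sort(key=lambda p: (-p.frequency, sorted(p.genes), sorted(p.conditions)))
    return patterns


def robust_patterns(
    patterns: list[SubsetPattern],
    n_datasets: int | None = None,
    threshold_fraction: float = 0.5,
) -> list[SubsetPattern]:
    """Threshold by support, then keep only maximal patterns.

    A kept pattern is maximal when no other kept pattern strictly contains
    it (gene-set and condition-set both supersets); the sub-pattern
    lattice below a maximal pattern is implied and not reported.
    """
    if not patterns:
        return []
    d = n_datasets or patterns[0].n_datasets
    kept = [p for p in patterns if p.frequency >= threshold_fraction * d]
    maximal = [
        p
        for p in kept
        if not any(q is not p and q.contains(p) for q in kept)
    ]
    maximal.sort(key=lambda p: (-p.frequency, sorted(p.genes), sorted(p.conditions)))
    return maximal


def group_patterns(robust: list[SubsetPattern]) -> list[RobustGroup]:
    """Merge robust patterns with identical gene sets into groups.

    The group's condition set is the union over its members; singleton
    patterns pass through as singleton groups.  Order-independent.
    """
    by_genes: dict[frozenset[str], list[SubsetPattern]] = {}
    for p in robust:
        by_genes.setdefault(p.genes, []).append(p)
    groups = []
    for genes, members in by_genes.items():
        members = sorted(members, key=lambda p: (-p.frequency, sorted(p.conditions)))
        conditions = frozenset().union(*(p.conditions for p in members))
        groups.append(RobustGroup(genes, conditions, tuple(members)))
    groups.sort(key=lambda g: (-g.support, sorted(g.genes)))
    return groups


def to_bipartite(groups: list[RobustGroup]) -> list[tuple[str, str, int, float]]:
    """Edge list (gene, condition, group_id, support); one edge per pair."""
    edges = []
    for gid, group in enumerate(groups, start=1):
        for gene in sorted(group.genes):
            for condition in sorted(group.conditions):
                edges.append((gene, condition, gid, group.support))
    return edges


def bipartite_graph(groups: list[RobustGroup]) -> nx.Graph:
    """networkx bipartite graph with group/support edge attributes."""
    g = nx.Graph()
    for gene, condition, gid, support in to_bipartite(groups):
        g.add_node(gene, bipartite="gene")
        g.add_node(condition, bipartite="condition")
        if g.has_edge(gene, condition):
            g[gene][condition]["groups"].append(gid)
        else:
            g.add_edge(gene, condition, groups=[gid], support=support)
    return g
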