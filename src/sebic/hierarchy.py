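"""Hierarchical clustering of genes and conditions with cophenetic validation.

Thin, typed layer over :mod:`scipy.cluster.hierarchy`: pairwise distances
(Euclidean, city block or correlation) on either axis of the normalized
expression matrix, agglomeration with single/complete/average linkage, the
cophenetic correlation coefficient as a goodness-of-tree check, Newick
export and an optional clustergram (heat map + trees) plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from .expression import ExpressionMatrix

__all__ = [
    "Dendrogram",
    "pairwise_distances",
    "agglomerate",
    "cophenetic_correlation",
    "plot_clustergram",
]

METRICS = ("euclidean", "cityblock", "correlation")
LINKAGES = ("single", "complete", "average")

Axis = Literal["genes", "conditions"]


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration result: scipy linkage matrix plus leaf labels.

    ``linkage_matrix`` rows are (left id, right id, merge height, cluster
    size) in scipy's convention; N leaves imply N-1 merges.
    """

    linkage_matrix: np.ndarray = field(repr=False)
    labels: tuple[str, ...]
    method: str

    def __post_init__(self) -> None:
        z = np.asarray(self.linkage_matrix, dtype=float)
        object.__setattr__(self, "linkage_matrix", z)
        if z.shape != (len(self.labels) - 1, 4):
            raise ValueError("linkage matrix shape does not match label count")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def leaf_order(self) -> list[str]:
        order = sch.leaves_list(self.linkage_matrix)
        return [self.labels[i] for i in order]

    def cut(self, height: float) -> dict[str, int]:
        """Flat partition: label -> cluster id, cutting at ``height``."""
        assign = sch.fcluster(self.linkage_matrix, t=height, criterion="distance")
        return {lab: int(c) for lab, c in zip(self.labels, assign)}

    def to_newick(self) -> str:
        """Newick string with branch lengths (half the merge-height gaps)."""
        tree = sch.to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = parent_height - (node.dist if not node.is_leaf() else 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        root = tree
        left = walk(root.left, root.dist)
        right = walk(root.right, root.dist)
        return f"({left},{right});"


def _matrix_for_axis(x: ExpressionMatrix, axis: Axis) -> tuple[np.ndarray, tuple[str, ...]]:
    if axis == "genes":
        return x.values, x.gene_ids
    if axis == "conditions":
        return x.values.T, x.condition_ids
    raise ValueError(f"unknown axis {axis!r}; expected 'genes' or 'conditions'")


def pairwise_distances(
    x: ExpressionMatrix, axis: Axis = "genes", metric: str = "euclidean"
) -> np.ndarray:
    """Square symmetric distance matrix over genes or conditions."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    values, _ = _matrix_for_axis(x, axis)
    return squareform(pdist(values, metric=metric))


def agglomerate(
    d: np.ndarray,
    linkage: str = "average",
    labels: tuple[str, ...] | None = None,
) -> Dendrogram:
    """Agglomerative clustering of a square distance matrix."""
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; expected one of {LINKAGES}")
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if labels is None:
        labels = tuple(str(i) for i in range(d.shape[0]))
    z = sch.linkage(squareform(d, checks=False), method=linkage)
    return Dendrogram(linkage_matrix=z, labels=tuple(labels), method=linkage)


def cophenetic_correlation(t: Dendrogram, d: np.ndarray) -> float:
    """Pearson correlation between original and cophenetic distances.

    Values near 1 mean the tree faithfully represents the distance matrix;
    trees with coefficients above roughly 0.9 are conventionally accepted.
    """
    d = np.asarray(d, dtype=float)
    if t.n_leaves < 3:
        raise ValueError("cophenetic correlation undefined for fewer than 3 leaves")
    if d.shape != (t.n_leaves, t.n_leaves):
        raise ValueError("distance matrix does not match the tree's leaves")
    c, _ = sch.cophenet(t.linkage_matrix, squareform(d, checks=False))
    return float(c)


def plot_clustergram(
    x: ExpressionMatrix,
    gene_tree: Dendrogram,
    condition_tree: Dendrogram,
    path: str,
    cmap: str = "RdBu_r",
) -> None:
    """Heat map reordered by both dendrograms, trees drawn in the margins."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gorder = sch.leaves_list(gene_tree.linkage_matrix)
    corder = sch.leaves_list(condition_tree.linkage_matrix)
    fig = plt.figure(figsize=(9, 7))
    ax_gtree = fig.add_axes([0.02, 0.1, 0.13, 0.6])
    ax_ctree = fig.add_axes([0.2, 0.75, 0.6, 0.2])
    ax_heat = fig.add_axes([0.2, 0.1, 0.6, 0.6])
    ax_cbar = fig.add_axes([0.84, 0.1, 0.02, 0.6])
    sch.dendrogram(gene_tree.linkage_matrix, orientation="left", ax=ax_gtree, no_labels=True)
    sch.dendrogram(condition_tree.linkage_matrix, ax=ax_ctree, no_labels=True)
    ax_gtree.set_axis_off()
    ax_ctree.set_axis_off()
    data = x.values[np.ix_(gorder[::-1], corder)]
    im = ax_heat.imshow(data, aspect="auto", cmap=cmap)
    ax_heat.set_yticks(range(len(gorder)), [x.gene_ids[i] for i in gorder[::-1]], fontsize=7)
    ax_heat.set_xticks(
        range(len(corder)), [x.condition_ids[j] for j in corder], rotation=90, fontsize=7
    )
    fig.colorbar(im, cax=ax_cbar)
    fig.savefig(path, dpi=150)
    plt.close(fig)
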