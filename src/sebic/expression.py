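"""Expression-data containers and qRT-PCR fold-change quantification.

The raw input of the pipeline is a table of qRT-PCR cycle times (Ct) per
(gene, condition, replicate), including a housekeeping gene and an
undifferentiated control condition.  Relative expression is quantified by
the standard comparative-Ct method::

    fold change = 2 ** (-ddCt)
    ddCt = (Ct_target - Ct_housekeeping)_sample
         - (Ct_target - Ct_housekeeping)_control

Fold changes per replicate form a genes x conditions x replicates tensor
(:class:`ReplicatedExpression`); averaging replicates gives the
genes x conditions matrix (:class:`ExpressionMatrix`) that all clustering
stages analyse, optionally log2-transformed and row z-scored.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROWTH_FACTORS",
    "condition_labels",
    "parse_condition_label",
    "CtTable",
    "ReplicatedExpression",
    "ExpressionMatrix",
    "fold_change_from_ct",
    "mean_matrix",
    "normalize_rows",
    "log2_matrix",
    "load_wide_matrix",
    "write_wide_matrix",
    "load_replicates_long",
    "write_replicates_long",
    "load_ct_table",
]

#: Canonical order of the four growth factors added on top of the constant
#: activin baseline: FGF2, BMP4, PI3K-inhibitor, WNT3A.
GROWTH_FACTORS: tuple[str, ...] = ("F", "B", "P", "W")


def condition_labels(factors: Sequence[str] = GROWTH_FACTORS) -> list[str]:
    """All non-empty factor combinations as ``+``-joined labels.

    Four factors give the 15 experimental conditions of the endoderm
    induction screen (activin is an implicit constant and is not written).
    Ordered by combination size, then by canonical factor order.
    """
    labels = []
    for r in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, r):
            labels.append("+".join(combo))
    return labels


def parse_condition_label(label: str, factors: Sequence[str] = GROWTH_FACTORS) -> frozenset[str]:
    """Parse a ``+``-joined condition label into its factor set.

    Raises ``ValueError`` on unknown factors, duplicates or empty labels.
    The bare label ``"A"`` (activin only) is accepted as the empty factor
    set for user data that includes the baseline condition.
    """
    if label == "A":
        return frozenset()
    parts = label.split("+")
    if any(p == "" for p in parts):
        raise ValueError(f"empty factor in condition label {label!r}")
    unknown = [p for p in parts if p not in factors]
    if unknown:
        raise ValueError(f"unknown factor(s) {unknown} in condition label {label!r}")
    if len(set(parts)) != len(parts):
        raise ValueError(f"duplicate factor in condition label {label!r}")
    return frozenset(parts)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CtTable:
    """Long-format qRT-PCR cycle-time records.

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``gene, condition, replicate, ct_target, ct_housekeeping``.
    control_condition : str
        Label of the control sample (undifferentiated cells) against which
        ddCt is computed.
    housekeeping_gene : str
        Name of the reference gene whose Ct is already paired per record.
    """

    records: pd.DataFrame
    control_condition: str
    housekeeping_gene: str = "GAPDH"

    def __post_init__(self) -> None:
        required = ["gene", "condition", "replicate", "ct_target", "ct_housekeeping"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise ValueError(f"CtTable records missing columns {missing}")
        dup = self.records.duplicated(subset=["gene", "condition", "replicate"])
        if dup.any():
            bad = self.records.loc[dup, ["gene", "condition", "replicate"]].iloc[0]
            raise ValueError(
                f"duplicate Ct record for gene={bad['gene']!r} "
                f"condition={bad['condition']!r} replicate={bad['replicate']!r}"
            )
        ct = self.records[["ct_target", "ct_housekeeping"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
            raise ValueError("cycle times must be finite positive numbers")
        genes_with_control = set(
            self.records.loc[self.records["condition"] == self.control_condition, "gene"]
        )
        for gene in self.records["gene"].unique():
            if gene not in genes_with_control:
                raise ValueError(
                    f"gene {gene!r} has no Ct record for control condition "
                    f"{self.control_condition!r}"
                )


@dataclass(frozen=True)
class ReplicatedExpression:
    """Fold-change tensor genes x conditions x replicates.

    ``values`` is an N x M x Rmax float array, NaN-padded where a cell has
    fewer replicates than ``Rmax``.  Fold changes are strictly positive;
    every cell carries at least one replicate.
    """

    gene_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n, m = len(self.gene_ids), len(self.condition_ids)
        if n < 2 or m < 2:
            raise ValueError("need at least 2 genes and 2 conditions")
        if v.ndim != 3 or v.shape[:2] != (n, m):
            raise ValueError(f"values shape {v.shape} does not match labels ({n}, {m}, R)")
        if len(set(self.gene_ids)) != n:
            raise ValueError("duplicate gene labels")
        if len(set(self.condition_ids)) != m:
            raise ValueError("duplicate condition labels")
        counts = np.sum(~np.isnan(v), axis=2)
        if np.any(counts == 0):
            i, j = np.argwhere(counts == 0)[0]
            raise ValueError(
                f"cell ({self.gene_ids[i]!r}, {self.condition_ids[j]!r}) has no replicates"
            )
        finite = v[~np.isnan(v)]
        if np.any(finite <= 0) or not np.all(np.isfinite(finite)):
            raise ValueError("fold changes must be strictly positive and finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    @property
    def replicate_counts(self) -> np.ndarray:
        """N x M integer array of available replicates per cell."""
        return np.sum(~np.isnan(self.values), axis=2)

    def cell_replicates(self, i: int, j: int) -> np.ndarray:
        """The observed replicate fold changes of cell (i, j)."""
        row = self.values[i, j]
        return row[~np.isnan(row)]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x conditions matrix analysed by the clustering stages."""

    gene_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    normalized: bool = False
    log2: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n, m = len(self.gene_ids), len(self.condition_ids)
        if v.shape != (n, m):
            raise ValueError(f"values shape {v.shape} does not match labels ({n}, {m})")
        if len(set(self.gene_ids)) != n:
            raise ValueError("duplicate gene labels")
        if len(set(self.condition_ids)) != m:
            raise ValueError("duplicate condition labels")
        if not np.all(np.isfinite(v)):
            raise ValueError("matrix values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.condition_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **kwargs) -> "ExpressionMatrix":
        return cls(
            gene_ids=tuple(str(g) for g in frame.index),
            condition_ids=tuple(str(c) for c in frame.columns),
            values=frame.to_numpy(dtype=float),
            **kwargs,
        )


# ---------------------------------------------------------------------------
# Quantification and normalization
# ---------------------------------------------------------------------------


def fold_change_from_ct(ct: CtTable) -> ReplicatedExpression:
    """Comparative-Ct quantification of a :class:`CtTable`.

    Target and housekeeping Ct are paired within the same replicate; the
    control dCt of each gene is the mean over the control replicates, so a
    single-replicate control computed against itself gives fold change 1
    exactly.
    """
    rec = ct.records.copy()
    rec["dct"] = rec["ct_target"].astype(float) - rec["ct_housekeeping"].astype(float)
    control = rec[rec["condition"] == ct.control_condition]
    control_dct = control.groupby("gene")["dct"].mean()

    genes = list(dict.fromkeys(rec["gene"]))
    conditions = list(dict.fromkeys(rec["condition"]))
    rmax = int(rec.groupby(["gene", "condition"]).size().max())
    values = np.full((len(genes), len(conditions), rmax), np.nan)
    gi = {g: i for i, g in enumerate(genes)}
    cj = {c: j for j, c in enumerate(conditions)}
    for (gene, condition), grp in rec.groupby(["gene", "condition"], sort=False):
        ddct = grp["dct"].to_numpy() - control_dct[gene]
        values[gi[gene], cj[condition], : len(ddct)] = 2.0 ** (-ddct)
    return ReplicatedExpression(tuple(genes), tuple(conditions), values)


def mean_matrix(data: ReplicatedExpression) -> ExpressionMatrix:
    """Arithmetic mean over replicates, per cell."""
    with np.errstate(invalid="ignore"):
        means = np.nanmean(data.values, axis=2)
    return ExpressionMatrix(data.gene_ids, data.condition_ids, means)


def log2_matrix(x: ExpressionMatrix) -> ExpressionMatrix:
    """log2 transform of a positive (fold-change scale) matrix."""
    if x.log2:
        return x
    if np.any(x.values <= 0):
        raise ValueError("log2 transform requires strictly positive values")
    return replace(x, values=np.log2(x.values), log2=True)


def normalize_rows(x: ExpressionMatrix, ddof: int = 0) -> ExpressionMatrix:
    """Row z-scoring: every gene gets mean 0 and standard deviation 1.

    Uses the population standard deviation (``ddof=0``) by default; the
    convention is configurable and the contract (mean 0, sd 1 under the
    declared convention) holds either way.  Idempotent to 1e-9.
    """
    v = x.values
    sd = v.std(axis=1, ddof=ddof)
    if np.any(sd == 0):
        i = int(np.argwhere(sd == 0)[0][0])
        raise ValueError(f"gene {x.gene_ids[i]!r} has constant expression; cannot scale")
    z = (v - v.mean(axis=1, keepdims=True)) / sd[:, None]
    return replace(x, values=z, normalized=True)


def analysis_matrix(
    data: ReplicatedExpression, *, log2: bool = True, normalize: bool = True, ddof: int = 0
) -> ExpressionMatrix:
    """Mean matrix on the analysis scale: optional log2, then row z-score."""
    x = mean_matrix(data)
    if log2:
        x = log2_matrix(x)
    if normalize:
        x = normalize_rows(x, ddof=ddof)
    return x


# ---------------------------------------------------------------------------
# Delimited-text IO
# ---------------------------------------------------------------------------


def _sniff_delimiter(path: str) -> str:
    with open(path, newline="") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def load_wide_matrix(path: str, **kwargs) -> ExpressionMatrix:
    """Read a wide matrix: header of condition labels, first column genes."""
    delim = _sniff_delimiter(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delim))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    conditions = header[1:]
    if len(set(conditions)) != len(conditions):
        raise ValueError(f"{path}:1: duplicate condition labels")
    genes: list[str] = []
    values: list[list[float]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ValueError(
                f"{path}:{lineno}: ragged row ({len(row)} fields, expected {len(header)})"
            )
        gene = row[0]
        if gene in genes:
            raise ValueError(f"{path}:{lineno}: duplicate gene label {gene!r}")
        genes.append(gene)
        try:
            values.append([float(v) for v in row[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    return ExpressionMatrix(tuple(genes), tuple(conditions), np.array(values), **kwargs)


def write_wide_matrix(x: ExpressionMatrix, path: str, delimiter: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["gene", *x.condition_ids])
        for gene, row in zip(x.gene_ids, x.values):
            w.writerow([gene, *(repr(float(v)) for v in row)])


def load_replicates_long(path: str) -> ReplicatedExpression:
    """Read a long-format replicate table: gene, condition, replicate, value."""
    delim = _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=delim)
    required = ["gene", "condition", "replicate", "value"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if frame.duplicated(subset=["gene", "condition", "replicate"]).any():
        raise ValueError(f"{path}: duplicate (gene, condition, replicate) record")
    genes = list(dict.fromkeys(frame["gene"].astype(str)))
    conditions = list(dict.fromkeys(frame["condition"].astype(str)))
    rmax = int(frame.groupby(["gene", "condition"]).size().max())
    values = np.full((len(genes), len(conditions), rmax), np.nan)
    gi = {g: i for i, g in enumerate(genes)}
    cj = {c: j for j, c in enumerate(conditions)}
    for (gene, condition), grp in frame.groupby(["gene", "condition"], sort=False):
        vals = grp["value"].to_numpy(dtype=float)
        values[gi[str(gene)], cj[str(condition)], : len(vals)] = vals
    return ReplicatedExpression(tuple(genes), tuple(conditions), values)


def write_replicates_long(data: ReplicatedExpression, path: str, delimiter: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["gene", "condition", "replicate", "value"])
        for i, gene in enumerate(data.gene_ids):
            for j, condition in enumerate(data.condition_ids):
                for r, v in enumerate(data.cell_replicates(i, j), start=1):
                    w.writerow([gene, condition, f"r{r}", repr(float(v))])


def load_ct_table(path: str, control_condition: str, housekeeping_gene: str = "GAPDH") -> CtTable:
    """Read a long-format Ct table: gene, condition, replicate, ct_target, ct_housekeeping."""
    delim = _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=delim)
    return CtTable(frame, control_condition=control_condition, housekeeping_gene=housekeeping_gene)
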