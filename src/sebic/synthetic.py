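"""Synthetic replicate fold-change tensors with implanted biclusters.

The generator emulates a small qRT-PCR differentiation screen — by default
12 transcription-factor markers across the 15 non-empty combinations of
four growth factors, 3 replicates per cell — and implants additive-coherent
biclusters with known ground truth.  Signal is defined on the log2
fold-change scale, where additive row/column offsets are exactly the
coherence the mean-squared-residue score measures, and exponentiated back
to the strictly positive fold-change scale:

    log2 value(i, j) = a_i + b_j + eps            inside an implant
    log2 value(i, j) ~ N(mu_bg, sd_bg^2)          background
    replicate(i, j, r) = value(i, j) + N(0, sd_rep^2)

With pattern and replicate noise at zero, every implant is an exactly
additive (zero-residue) submatrix of the log2 mean matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .expression import GROWTH_FACTORS, ReplicatedExpression, condition_labels

__all__ = [
    "ImplantSpec",
    "SyntheticSpec",
    "GroundTruth",
    "generate_dataset",
    "contrast_offsets",
    "endoderm_benchmark_spec",
    "DEFAULT_MARKERS",
]


def contrast_offsets(k: int, sd: float = 1.5) -> tuple[float, ...]:
    """Two-level offsets (half low, half high) with population sd exactly ``sd``.

    The natural shape for a condition contrast — a condition either
    activates the co-regulated module or it does not — and, at a fixed
    signal sd, the most identifiable one: no near-zero offset column that
    a variance-seeking search would prefer to drop.
    """
    if k < 2:
        raise ValueError("need k >= 2")
    u = np.ones(k)
    u[: k // 2] = -1.0
    return tuple(float(v) for v in sd * u / u.std())

#: Marker panel of the default benchmark: pluripotency (OCT4), mesendoderm
#: (BRACHYURY), definitive endoderm (CXCR4, SOX17, CER, FOXA2) and pancreatic
#: progenitor markers (PTF1A, PDX1, GATA4, HNF1B, HNF4A, HNF6).
DEFAULT_MARKERS: tuple[str, ...] = (
    "OCT4",
    "BRACHYURY",
    "CXCR4",
    "SOX17",
    "CER",
    "FOXA2",
    "PTF1A",
    "PDX1",
    "GATA4",
    "HNF1B",
    "HNF4A",
    "HNF6",
)


@dataclass(frozen=True)
class ImplantSpec:
    """One implanted additive pattern.

    ``gene_offsets``/``condition_offsets`` (log2 units) may be given
    explicitly; when ``None`` they are drawn once from N(0, offset_sd^2)
    using the dataset seed.  ``noise_sd`` is the within-pattern residual
    noise (log2 units).
    """

    genes: tuple[int, ...]
    conditions: tuple[int, ...]
    gene_offsets: tuple[float, ...] | None = None
    condition_offsets: tuple[float, ...] | None = None
    noise_sd: float = 0.0
    offset_sd: float = 1.5

    def __post_init__(self) -> None:
        if len(self.genes) < 2 or len(self.conditions) < 2:
            raise ValueError("an implant needs at least 2 genes and 2 conditions")
        if self.noise_sd < 0 or self.offset_sd < 0:
            raise ValueError("noise/offset sd must be >= 0")
        if self.gene_offsets is not None and len(self.gene_offsets) != len(self.genes):
            raise ValueError("gene_offsets length mismatch")
        if self.condition_offsets is not None and len(self.condition_offsets) != len(
            self.conditions
        ):
            raise ValueError("condition_offsets length mismatch")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic dataset."""

    n_genes: int = 12
    n_conditions: int = 15
    n_replicates: int = 3
    background_mean: float = 0.0
    background_sd: float = 1.0
    replicate_sd: float = 0.5
    implants: tuple[ImplantSpec, ...] = ()
    gene_ids: tuple[str, ...] | None = None
    condition_ids: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_conditions < 2:
            raise ValueError("need at least 2 genes and 2 conditions")
        if self.n_replicates < 1:
            raise ValueError("need at least 1 replicate")
        if self.background_sd < 0 or self.replicate_sd < 0:
            raise ValueError("noise sd must be >= 0")
        for imp in self.implants:
            if max(imp.genes) >= self.n_genes or min(imp.genes) < 0:
                raise ValueError(f"implant gene indices {imp.genes} out of range")
            if max(imp.conditions) >= self.n_conditions or min(imp.conditions) < 0:
                raise ValueError(f"implant condition indices {imp.conditions} out of range")
        if self.gene_ids is not None and len(self.gene_ids) != self.n_genes:
            raise ValueError("gene_ids length mismatch")
        if self.condition_ids is not None and len(self.condition_ids) != self.n_conditions:
            raise ValueError("condition_ids length mismatch")

    def resolved_gene_ids(self) -> tuple[str, ...]:
        if self.gene_ids is not None:
            return self.gene_ids
        return tuple(f"G{i + 1}" for i in range(self.n_genes))

    def resolved_condition_ids(self) -> tuple[str, ...]:
        if self.condition_ids is not None:
            return self.condition_ids
        if self.n_conditions == 15:
            return tuple(condition_labels(GROWTH_FACTORS))
        return tuple(f"C{j + 1}" for j in range(self.n_conditions))


@dataclass(frozen=True)
class GroundTruth:
    """Implanted (gene-set, condition-set) pairs by label, plus overlap flag."""

    patterns: tuple[tuple[frozenset[str], frozenset[str]], ...]
    overlapping: bool = False

    def to_json(self) -> str:
        payload = [
            {"genes": sorted(g), "conditions": sorted(c)} for g, c in self.patterns
        ]
        return json.dumps({"patterns": payload, "overlapping": self.overlapping}, sort_keys=True)


def generate_dataset(spec: SyntheticSpec) -> tuple[ReplicatedExpression, GroundTruth]:
    """Draw one replicate fold-change tensor from a :class:`SyntheticSpec`.

    Deterministic given ``spec.seed``.  Overlapping implants are applied in
    order (later implants overwrite shared cells) and flagged in the
    returned :class:`GroundTruth`.
    """
    rng = np.random.default_rng(spec.seed)
    n, m, r = spec.n_genes, spec.n_conditions, spec.n_replicates
    log2_cells = rng.normal(spec.background_mean, spec.background_sd, size=(n, m))

    covered = np.zeros((n, m), dtype=int)
    for imp in spec.implants:
        gi = np.asarray(imp.genes)
        cj = np.asarray(imp.conditions)
        a = (
            np.asarray(imp.gene_offsets, dtype=float)
            if imp.gene_offsets is not None
            else rng.normal(0.0, imp.offset_sd, size=len(gi))
        )
        b = (
            np.asarray(imp.condition_offsets, dtype=float)
            if imp.condition_offsets is not None
            else rng.normal(0.0, imp.offset_sd, size=len(cj))
        )
        eps = (
            rng.normal(0.0, imp.noise_sd, size=(len(gi), len(cj)))
            if imp.noise_sd > 0
            else np.zeros((len(gi), len(cj)))
        )
        log2_cells[np.ix_(gi, cj)] = a[:, None] + b[None, :] + eps
        covered[np.ix_(gi, cj)] += 1

    log2_reps = log2_cells[:, :, None] + (
        rng.normal(0.0, spec.replicate_sd, size=(n, m, r)) if spec.replicate_sd > 0 else 0.0
    )
    values = np.exp2(log2_reps)

    genes = spec.resolved_gene_ids()
    conditions = spec.resolved_condition_ids()
    patterns = tuple(
        (
            frozenset(genes[i] for i in imp.genes),
            frozenset(conditions[j] for j in imp.conditions),
        )
        for imp in spec.implants
    )
    truth = GroundTruth(patterns=patterns, overlapping=bool(np.any(covered > 1)))
    data = ReplicatedExpression(genes, conditions, values)
    return data, truth


def endoderm_benchmark_spec(
    *,
    replicate_sd: float = 0.5,
    pattern_noise_sd: float = 0.0,
    offset_sd: float = 1.5,
    signal_scale: float = 1.0,
    seed: int = 0,
) -> SyntheticSpec:
    """The default 12-marker x 15-condition benchmark.

    Two additive implants mirror the shape of the robust groups the method
    is meant to find in an endoderm induction screen: an early/late marker
    pair (CER, HNF6) under four conditions and a late-marker pair
    (HNF6, HNF4A) under three conditions, sharing the HNF6 marker.  Offsets
    are two-level contrasts with population sd exactly ``offset_sd`` (see
    :func:`contrast_offsets`); ``signal_scale=0`` removes the implants'
    signal entirely (pure-noise control) while keeping the ground-truth
    bookkeeping.
    """
    genes = DEFAULT_MARKERS
    conditions = tuple(condition_labels(GROWTH_FACTORS))
    gidx = {g: i for i, g in enumerate(genes)}
    cidx = {c: j for j, c in enumerate(conditions)}

    def implant(gs: Sequence[str], cs: Sequence[str]) -> ImplantSpec:
        return ImplantSpec(
            genes=tuple(gidx[g] for g in gs),
            conditions=tuple(cidx[c] for c in cs),
            gene_offsets=tuple(signal_scale * v for v in contrast_offsets(len(gs), offset_sd)),
            condition_offsets=tuple(
                signal_scale * v for v in contrast_offsets(len(cs), offset_sd)
            ),
            noise_sd=pattern_noise_sd,
            offset_sd=offset_sd,
        )

    implants = (
        implant(("CER", "HNF6"), ("F", "F+W", "B+P", "B+P+W")),
        implant(("HNF6", "HNF4A"), ("F+B", "F+P", "P+W")),
    )
    return SyntheticSpec(
        n_genes=len(genes),
        n_conditions=len(conditions),
        n_replicates=3,
        background_sd=1.0,
        replicate_sd=replicate_sd,
        implants=implants,
        gene_ids=genes,
        condition_ids=conditions,
        seed=seed,
    )
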