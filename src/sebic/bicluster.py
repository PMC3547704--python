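"""Bicluster quality metrics and sequential evolutionary bicluster search.

A bicluster B(I, J) is a pair of index sets into an expression matrix X.
Its coherence is scored by the Cheng–Church mean squared residue

    r_ij = e_ij - e_iJ - e_Ij + e_IJ
    MSR(B) = mean of r_ij^2 over the |I| x |J| elements,

which is zero exactly when the submatrix is additive (e_ij = a_i + b_j).
Constant biclusters are penalized through the row variance (mean squared
deviation from the gene base); re-discovery of previously accepted
biclusters is penalized through a per-element coverage count.  Candidates
are ranked by the fitness (minimized)

    F(B) = MSR(B)/delta + 1/row_variance(B) + w_d + penalty(B)
    w_d  = Wr * delta/|I| + Wc * delta/|J|

so that coherent, high-variance, large, little-overlapping biclusters win.
The search encodes B as an (N + M)-bit chromosome and runs a generational
genetic algorithm; sequential extraction re-runs the search after
incrementing coverage over each accepted bicluster's cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .expression import ExpressionMatrix

__all__ = [
    "Bicluster",
    "CoverageMatrix",
    "BiclusterConfig",
    "mean_squared_residue",
    "row_variance",
    "overlap_penalty",
    "fitness",
    "ga_search",
    "sequential_extract",
    "exhaustive_search",
    "jaccard",
]


@dataclass(frozen=True, order=True)
class Bicluster:
    """Index sets (rows, cols) into an N x M expression matrix."""

    rows: tuple[int, ...]
    cols: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(sorted(self.rows)))
        object.__setattr__(self, "cols", tuple(sorted(self.cols)))
        if len(set(self.rows)) != len(self.rows) or len(set(self.cols)) != len(self.cols):
            raise ValueError("duplicate indices in bicluster")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.cols)

    @property
    def volume(self) -> int:
        return self.n_rows * self.n_cols

    def submatrix(self, values: np.ndarray) -> np.ndarray:
        return values[np.ix_(self.rows, self.cols)]

    def gene_labels(self, x: ExpressionMatrix) -> tuple[str, ...]:
        return tuple(x.gene_ids[i] for i in self.rows)

    def condition_labels(self, x: ExpressionMatrix) -> tuple[str, ...]:
        return tuple(x.condition_ids[j] for j in self.cols)

    def to_dict(self, x: ExpressionMatrix) -> dict:
        return {
            "genes": list(self.gene_labels(x)),
            "conditions": list(self.condition_labels(x)),
            "msr": mean_squared_residue(self, x),
            "row_variance": row_variance(self, x),
        }


class CoverageMatrix:
    """Per-element count of previously accepted biclusters containing a cell.

    Starts all-zero and is only ever incremented; drives the overlap
    penalty of sequential extraction.
    """

    def __init__(self, n_genes: int, n_conditions: int) -> None:
        self.counts = np.zeros((n_genes, n_conditions), dtype=int)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def add(self, b: Bicluster) -> None:
        self.counts[np.ix_(b.rows, b.cols)] += 1

    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class BiclusterConfig:
    """Scoring and search parameters.

    delta is the residue acceptance threshold; biclusters with MSR above
    delta are never reported.  Wr/Wc weight the size reward.  The GA block
    uses standard settings for a small (N + M)-bit search space and is
    fully overridable.
    """

    delta: float = 1.5
    w_r: float = 1.0
    w_c: float = 1.0
    penalty_form: Literal["exp", "linear"] = "exp"
    size_reward: Literal["delta_over_size", "inverse_size"] = "delta_over_size"
    population_size: int = 100
    generations: int = 200
    crossover_prob: float = 0.7
    mutation_prob: float | None = None  # default 1/(N+M)
    elitism: int = 1
    tournament_size: int = 2
    stall_generations: int = 30
    n_restarts: int = 3
    immigrant_fraction: float = 0.1
    local_search: bool = True

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if not (0.0 <= self.crossover_prob <= 1.0):
            raise ValueError("crossover_prob must be in [0, 1]")
        if self.mutation_prob is not None and not (0.0 <= self.mutation_prob <= 1.0):
            raise ValueError("mutation_prob must be in [0, 1]")
        if self.population_size < 2 or self.generations < 1:
            raise ValueError("population_size >= 2 and generations >= 1 required")
        if self.penalty_form not in ("exp", "linear"):
            raise ValueError(f"unknown penalty_form {self.penalty_form!r}")
        if self.size_reward not in ("delta_over_size", "inverse_size"):
            raise ValueError(f"unknown size_reward {self.size_reward!r}")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if not (0.0 <= self.immigrant_fraction < 1.0):
            raise ValueError("immigrant_fraction must be in [0, 1)")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


# ---------------------------------------------------------------------------
# Scalar metrics
# ---------------------------------------------------------------------------


def _check_bicluster(b: Bicluster, shape: tuple[int, int]) -> None:
    if b.n_rows < 1 or b.n_cols < 1:
        raise ValueError("degenerate bicluster (empty row or column set)")
    if b.rows[-1] >= shape[0] or b.cols[-1] >= shape[1]:
        raise ValueError(f"bicluster indices out of range for matrix {shape}")


def _values(x: ExpressionMatrix | np.ndarray) -> np.ndarray:
    return x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, dtype=float)


def mean_squared_residue(b: Bicluster, x: ExpressionMatrix | np.ndarray) -> float:
    """Cheng–Church mean squared residue of the submatrix."""
    v = _values(x)
    _check_bicluster(b, v.shape)
    sub = b.submatrix(v)
    row_means = sub.mean(axis=1, keepdims=True)
    col_means = sub.mean(axis=0, keepdims=True)
    overall = sub.mean()
    residue = sub - row_means - col_means + overall
    return float(np.mean(residue**2))


def row_variance(b: Bicluster, x: ExpressionMatrix | np.ndarray) -> float:
    """Mean squared deviation of each element from its gene (row) base."""
    v = _values(x)
    _check_bicluster(b, v.shape)
    sub = b.submatrix(v)
    return float(np.mean((sub - sub.mean(axis=1, keepdims=True)) ** 2))


def _penalty_weights(counts: np.ndarray, form: str) -> np.ndarray:
    if form == "exp":
        return np.expm1(counts.astype(float))
    return counts.astype(float)


def overlap_penalty(
    b: Bicluster, cov: CoverageMatrix, form: str = "exp"
) -> float:
    """Sum over the bicluster's cells of the coverage weight wp.

    wp is 0 for uncovered cells and strictly increasing in the coverage
    count: exp(count) - 1 by default, or the count itself (linear form).
    """
    _check_bicluster(b, cov.shape)
    w = _penalty_weights(cov.counts, form)
    return float(b.submatrix(w).sum())


def _size_reward(n_rows: int, n_cols: int, cfg: BiclusterConfig) -> float:
    if cfg.size_reward == "delta_over_size":
        return cfg.w_r * cfg.delta / n_rows + cfg.w_c * cfg.delta / n_cols
    return cfg.w_r / n_rows + cfg.w_c / n_cols


def fitness(
    b: Bicluster,
    x: ExpressionMatrix | np.ndarray,
    cov: CoverageMatrix | None = None,
    cfg: BiclusterConfig | None = None,
) -> float:
    """Minimized fitness; +inf sentinel for infeasible candidates.

    Infeasible means fewer than 2 rows or columns, or zero row variance
    (a trivial constant bicluster).
    """
    cfg = cfg or BiclusterConfig()
    if b.n_rows < 2 or b.n_cols < 2:
        return float("inf")
    var = row_variance(b, x)
    if var == 0.0:
        return float("inf")
    pen = 0.0 if cov is None else overlap_penalty(b, cov, cfg.penalty_form)
    return (
        mean_squared_residue(b, x) / cfg.delta
        + 1.0 / var
        + _size_reward(b.n_rows, b.n_cols, cfg)
        + pen
    )


def jaccard(a: Iterable, b: Iterable) -> float:
    """Jaccard index of two index/label sets."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


# ---------------------------------------------------------------------------
# Batched population evaluation
# ---------------------------------------------------------------------------


def _evaluate_population(
    pop: np.ndarray,
    values: np.ndarray,
    penalty_w: np.ndarray,
    cfg: BiclusterConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Fitness and MSR for every chromosome in one vectorized pass.

    ``pop`` is a P x (N+M) boolean array.  Returns (fitness, msr) arrays of
    length P; infeasible chromosomes get fitness +inf and msr +inf.
    """
    n, m = values.shape
    rows = pop[:, :n]
    cols = pop[:, n:]
    n_i = rows.sum(axis=1)
    n_j = cols.sum(axis=1)
    feasible = (n_i >= 2) & (n_j >= 2)

    p = pop.shape[0]
    fit = np.full(p, np.inf)
    msr = np.full(p, np.inf)
    if not feasible.any():
        return fit, msr

    r = rows[feasible].astype(float)
    c = cols[feasible].astype(float)
    ni = n_i[feasible].astype(float)
    nj = n_j[feasible].astype(float)

    # e_iJ for all rows (q x N), e_Ij for all cols (q x M), e_IJ (q,)
    row_means = (c @ values.T) / nj[:, None]
    col_means = (r @ values) / ni[:, None]
    overall = np.einsum("qn,qn->q", r, row_means) / ni

    resid = (
        values[None, :, :]
        - row_means[:, :, None]
        - col_means[:, None, :]
        + overall[:, None, None]
    )
    mask = r[:, :, None] * c[:, None, :]
    vol = ni * nj
    msr_f = np.einsum("qnm,qnm->q", resid**2, mask) / vol

    dev = values[None, :, :] - row_means[:, :, None]
    var_f = np.einsum("qnm,qnm->q", dev**2, mask) / vol

    pen_f = np.einsum("qn,nm,qm->q", r, penalty_w, c)

    if cfg.size_reward == "delta_over_size":
        wd = cfg.w_r * cfg.delta / ni + cfg.w_c * cfg.delta / nj
    else:
        wd = cfg.w_r / ni + cfg.w_c / nj

    fit_f = np.where(
        var_f > 0.0,
        msr_f / cfg.delta + np.divide(1.0, var_f, out=np.full_like(var_f, np.inf), where=var_f > 0) + wd + pen_f,
        np.inf,
    )
    fit[feasible] = fit_f
    msr[feasible] = msr_f
    return fit, msr


def _chromosome_key(chrom: np.ndarray) -> tuple:
    return tuple(np.flatnonzero(chrom))


def _hill_climb(
    chrom: np.ndarray,
    values: np.ndarray,
    penalty_w: np.ndarray,
    cfg: BiclusterConfig,
    max_steps: int = 64,
) -> tuple[np.ndarray, float, float]:
    """Steepest-descent single-bit refinement of one chromosome.

    Returns (chromosome, fitness, msr) at the reached local optimum.
    """
    bits = values.shape[0] + values.shape[1]
    eye = np.eye(bits, dtype=bool)
    cur = chrom.copy()
    cur_fit, cur_msr = (
        float(v[0]) for v in _evaluate_population(cur[None, :], values, penalty_w, cfg)
    )
    for _ in range(max_steps):
        neigh = cur[None, :] ^ eye
        fit, msr = _evaluate_population(neigh, values, penalty_w, cfg)
        k = int(np.argmin(fit))
        if fit[k] < cur_fit - 1e-12:
            cur = neigh[k]
            cur_fit, cur_msr = float(fit[k]), float(msr[k])
        else:
            break
    return cur, cur_fit, cur_msr


def _decode(chrom: np.ndarray, n: int) -> Bicluster:
    return Bicluster(
        rows=tuple(int(i) for i in np.flatnonzero(chrom[:n])),
        cols=tuple(int(j) for j in np.flatnonzero(chrom[n:])),
    )


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------


def _ga_once(
    values: np.ndarray,
    penalty_w: np.ndarray,
    cfg: BiclusterConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray | None, float]:
    """One GA run; returns (best acceptable chromosome or None, its fitness)."""
    n, m = values.shape
    bits = n + m
    p_mut = cfg.mutation_prob if cfg.mutation_prob is not None else 1.0 / bits

    pop = rng.random((cfg.population_size, bits)) < 0.5
    best_chrom: np.ndarray | None = None
    best_fit = np.inf
    best_raw = np.inf
    stall = 0
    climbed: set[tuple] = set()

    for _gen in range(cfg.generations):
        fit, msr = _evaluate_population(pop, values, penalty_w, cfg)

        # Lamarckian refinement: hill-climb the best few distinct
        # individuals; near-optimal candidates (e.g. an implanted pattern
        # plus one stray gene) are otherwise outcompeted before mutation
        # can clean them up.
        if cfg.local_search:
            n_climbed = 0
            for idx in np.argsort(fit, kind="stable"):
                if not np.isfinite(fit[idx]) or n_climbed >= 3:
                    break
                key = _chromosome_key(pop[idx])
                if key in climbed:
                    continue
                climbed.add(key)
                new, nf, nm = _hill_climb(pop[idx], values, penalty_w, cfg)
                climbed.add(_chromosome_key(new))
                pop[idx], fit[idx], msr[idx] = new, nf, nm
                n_climbed += 1

        # track best feasible-and-acceptable candidate seen anywhere
        ok = np.isfinite(fit) & (msr <= cfg.delta)
        improved = False
        raw_min = float(fit.min())
        if raw_min < best_raw - 1e-12:
            best_raw = raw_min
            improved = True
        if ok.any():
            order = np.flatnonzero(ok)
            cand = order[np.argmin(fit[order])]
            cand_fit = fit[cand]
            if cand_fit < best_fit - 1e-15:
                best_fit, best_chrom = cand_fit, pop[cand].copy()
                improved = True
            elif best_chrom is not None and np.isclose(cand_fit, best_fit, rtol=0, atol=1e-12):
                # tie-break: larger volume, then lexicographic index sets
                cur = _decode(best_chrom, n)
                new = _decode(pop[cand], n)
                if (new.volume, cur.rows, cur.cols) > (cur.volume, new.rows, new.cols):
                    best_chrom = pop[cand].copy()
        stall = 0 if improved else stall + 1
        if stall >= cfg.stall_generations:
            break

        # selection: binary tournament on fitness (minimize)
        draws = rng.integers(0, cfg.population_size, size=(cfg.population_size, cfg.tournament_size))
        winners = draws[np.arange(cfg.population_size), np.argmin(fit[draws], axis=1)]
        parents = pop[winners]

        # uniform crossover on consecutive pairs
        children = parents.copy()
        for k in range(0, cfg.population_size - 1, 2):
            if rng.random() < cfg.crossover_prob:
                swap = rng.random(bits) < 0.5
                a, b = children[k].copy(), children[k + 1].copy()
                children[k, swap], children[k + 1, swap] = b[swap], a[swap]

        # per-bit mutation
        flips = rng.random((cfg.population_size, bits)) < p_mut
        children ^= flips

        # random immigrants keep diversity after convergence
        n_imm = int(cfg.immigrant_fraction * cfg.population_size)
        if n_imm:
            children[-n_imm:] = rng.random((n_imm, bits)) < 0.5

        # elitism: reinsert current best-known chromosomes
        if cfg.elitism > 0:
            elite_idx = np.argsort(fit, kind="stable")[: cfg.elitism]
            children[: cfg.elitism] = pop[elite_idx]
        pop = children

    return best_chrom, best_fit


def ga_search(
    x: ExpressionMatrix | np.ndarray,
    cov: CoverageMatrix | None = None,
    cfg: BiclusterConfig | None = None,
    seed: int | np.random.SeedSequence | None = 0,
) -> Bicluster | None:
    """Evolve (N+M)-bit chromosomes and return the best feasible bicluster.

    Runs ``cfg.n_restarts`` independent GA populations (premature
    convergence is the main failure mode on rugged small landscapes) and
    keeps the overall best.  Feasible means at least 2 genes and 2
    conditions, positive row variance and MSR <= delta; returns ``None``
    when no such candidate is ever seen.  Deterministic given the seed.
    Ties on fitness are broken toward larger volume, then
    lexicographically smallest index sets.
    """
    cfg = cfg or BiclusterConfig()
    values = _values(x)
    n, m = values.shape
    penalty_w = (
        _penalty_weights(cov.counts, cfg.penalty_form)
        if cov is not None
        else np.zeros((n, m))
    )
    if cov is not None and cov.shape != (n, m):
        raise ValueError(f"coverage shape {cov.shape} does not match matrix {(n, m)}")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    best: Bicluster | None = None
    best_fit = np.inf
    for child in ss.spawn(cfg.n_restarts):
        chrom, fit_r = _ga_once(values, penalty_w, cfg, np.random.default_rng(child))
        if chrom is None:
            continue
        cand = _decode(chrom, n)
        if fit_r < best_fit - 1e-15:
            best, best_fit = cand, fit_r
        elif best is not None and np.isclose(fit_r, best_fit, rtol=0, atol=1e-12):
            if (cand.volume, best.rows, best.cols) > (best.volume, cand.rows, cand.cols):
                best = cand
    return best


def sequential_extract(
    x: ExpressionMatrix | np.ndarray,
    cfg: BiclusterConfig | None = None,
    k: int = 5,
    seed: int | np.random.SeedSequence | None = 0,
    cov: CoverageMatrix | None = None,
) -> list[Bicluster]:
    """Extract up to ``k`` biclusters sequentially.

    After each accepted bicluster the coverage counts of its cells are
    incremented, and the next search is penalized for re-using them.
    Stops early when a round finds nothing acceptable.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cfg = cfg or BiclusterConfig()
    values = _values(x)
    cov = cov or CoverageMatrix(*values.shape)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    round_seeds = ss.spawn(k)
    found: list[Bicluster] = []
    for r in range(k):
        b = ga_search(x, cov=cov, cfg=cfg, seed=round_seeds[r])
        if b is None:
            break
        found.append(b)
        cov.add(b)
    return found


def exhaustive_search(
    x: ExpressionMatrix | np.ndarray,
    cov: CoverageMatrix | None = None,
    cfg: BiclusterConfig | None = None,
    require_acceptable: bool = True,
) -> tuple[Bicluster | None, float]:
    """Brute-force global optimum over all row/column subsets (small N, M).

    Independent oracle for the GA: enumerates every bicluster with at
    least 2 rows and 2 columns and returns the fitness minimizer (subject
    to MSR <= delta when ``require_acceptable``), with the same
    tie-breaking as the GA.  Exponential cost; intended for N + M <= ~18.
    """
    cfg = cfg or BiclusterConfig()
    values = _values(x)
    n, m = values.shape
    if n + m > 22:
        raise ValueError("exhaustive search is limited to small matrices")
    penalty_w = (
        _penalty_weights(cov.counts, cfg.penalty_form)
        if cov is not None
        else np.zeros((n, m))
    )
    row_subsets = [s for s in range(1 << n) if bin(s).count("1") >= 2]
    col_subsets = [s for s in range(1 << m) if bin(s).count("1") >= 2]
    best: Bicluster | None = None
    best_fit = np.inf
    for rs in row_subsets:
        rows = tuple(i for i in range(n) if rs >> i & 1)
        chrom_rows = np.zeros(n, dtype=bool)
        chrom_rows[list(rows)] = True
        # evaluate all column subsets for this row set in one batch
        pop = np.zeros((len(col_subsets), n + m), dtype=bool)
        pop[:, :n] = chrom_rows
        for idx, cs in enumerate(col_subsets):
            for j in range(m):
                if cs >> j & 1:
                    pop[idx, n + j] = True
        fit, msr = _evaluate_population(pop, values, penalty_w, cfg)
        if require_acceptable:
            fit = np.where(msr <= cfg.delta, fit, np.inf)
        k = int(np.argmin(fit))
        if fit[k] < best_fit - 1e-15:
            best_fit = float(fit[k])
            best = _decode(pop[k], n)
        elif best is not None and np.isclose(fit[k], best_fit, rtol=0, atol=1e-12):
            new = _decode(pop[k], n)
            if (new.volume, best.rows, best.cols) > (best.volume, new.rows, new.cols):
                best = new
    if best is None:
        return None, float("inf")
    return best, best_fit
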