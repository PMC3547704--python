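"""Bicluster metrics against brute-force oracles; GA and sequential search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from sebic.bicluster import (
    Bicluster,
    BiclusterConfig,
    CoverageMatrix,
    exhaustive_search,
    fitness,
    ga_search,
    jaccard,
    mean_squared_residue,
    overlap_penalty,
    row_variance,
    sequential_extract,
)
from sebic.expression import analysis_matrix
from sebic.synthetic import ImplantSpec, SyntheticSpec, contrast_offsets, generate_dataset


def naive_msr(sub: np.ndarray) -> float:
    """Double-loop oracle for the mean squared residue."""
    n, m = sub.shape
    total = 0.0
    for i in range(n):
        for j in range(m):
            r = sub[i, j] - sub[i, :].mean() - sub[:, j].mean() + sub.mean()
            total += r * r
    return total / (n * m)


def naive_row_variance(sub: np.ndarray) -> float:
    n, m = sub.shape
    total = 0.0
    for i in range(n):
        for j in range(m):
            total += (sub[i, j] - sub[i, :].mean()) ** 2
    return total / (n * m)


class TestResidue:
    def test_two_by_two_example(self):
        x = np.array([[1.0, 2.0], [3.0, 5.0]])
        b = Bicluster((0, 1), (0, 1))
        assert mean_squared_residue(b, x) == pytest.approx(0.0625, abs=1e-12)

    def test_additive_submatrix_is_zero(self):
        a = np.array([0.5, -1.0, 2.0])
        c = np.array([1.0, 0.0, -2.0, 3.0])
        x = a[:, None] + c[None, :]
        b = Bicluster((0, 1, 2), (0, 1, 2, 3))
        assert mean_squared_residue(b, x) == pytest.approx(0.0, abs=1e-12)

    def test_constant_submatrix_is_zero(self):
        x = np.full((3, 3), 7.0)
        assert mean_squared_residue(Bicluster((0, 1), (0, 2)), x) == 0.0

    def test_matches_naive_oracle_on_random_submatrices(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            x = rng.normal(size=(10, 10))
            rows = tuple(np.sort(rng.choice(10, rng.integers(2, 6), replace=False)))
            cols = tuple(np.sort(rng.choice(10, rng.integers(2, 6), replace=False)))
            b = Bicluster(rows, cols)
            sub = b.submatrix(x)
            assert mean_squared_residue(b, x) == pytest.approx(naive_msr(sub), abs=1e-10)
            assert row_variance(b, x) == pytest.approx(naive_row_variance(sub), abs=1e-10)

    @given(
        a=hnp.arrays(np.float64, 4, elements=st.floats(-10, 10)),
        c=hnp.arrays(np.float64, 5, elements=st.floats(-10, 10)),
        scale=st.floats(0.1, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_shift_invariance_and_quadratic_scaling(self, a, c, scale):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(4, 5))
        b = Bicluster((0, 1, 2, 3), (0, 1, 2, 3, 4))
        base = mean_squared_residue(b, x)
        shifted = x + a[:, None] + c[None, :]
        assert mean_squared_residue(b, shifted) == pytest.approx(base, abs=1e-8)
        assert mean_squared_residue(b, x * scale) == pytest.approx(
            base * scale**2, rel=1e-9
        )

    def test_degenerate_bicluster_rejected(self):
        x = np.eye(4)
        with pytest.raises(ValueError):
            mean_squared_residue(Bicluster((), (0, 1)), x)


class TestRowVariance:
    def test_constant_rows_zero(self):
        x = np.array([[1.0, 1.0, 1.0], [4.0, 4.0, 4.0]])
        assert row_variance(Bicluster((0, 1), (0, 1, 2)), x) == 0.0

    def test_additive_three_by_five_example(self):
        a = np.array([1.0, 2.0, 3.0])
        c = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        x = a[:, None] + c[None, :]
        b = Bicluster((0, 1, 2), (0, 1, 2, 3, 4))
        assert row_variance(b, x) == pytest.approx(2.0)

    def test_single_condition_is_zero(self):
        x = np.random.default_rng(0).normal(size=(4, 4))
        assert row_variance(Bicluster((0, 1, 2), (2,)), x) == pytest.approx(0.0)


class TestPenalty:
    def test_zero_coverage_zero_penalty(self):
        cov = CoverageMatrix(4, 4)
        assert overlap_penalty(Bicluster((0, 1), (0, 1)), cov) == 0.0

    def test_fully_covered_two_by_two(self):
        cov = CoverageMatrix(4, 4)
        cov.add(Bicluster((0, 1), (0, 1)))
        pen = overlap_penalty(Bicluster((0, 1), (0, 1)), cov)
        assert pen == pytest.approx(4 * (np.e - 1))

    def test_monotone_in_coverage(self):
        cov = CoverageMatrix(4, 4)
        b = Bicluster((0, 1), (0, 1))
        cov.add(b)
        p1 = overlap_penalty(b, cov)
        cov.counts[0, 0] += 1
        assert overlap_penalty(b, cov) > p1

    def test_linear_form(self):
        cov = CoverageMatrix(4, 4)
        cov.add(Bicluster((0, 1), (0, 1)))
        assert overlap_penalty(Bicluster((0, 1), (0, 1)), cov, form="linear") == 4.0


class TestFitness:
    def test_worked_example(self):
        # zero-residue 3x5, row variance 2, no coverage:
        # F = 0 + 1/2 + (1.5/3 + 1.5/5) + 0 = 1.3
        a = np.array([1.0, 2.0, 3.0])
        c = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        x = np.zeros((6, 8))
        x[np.ix_([0, 1, 2], [0, 1, 2, 3, 4])] = a[:, None] + c[None, :]
        b = Bicluster((0, 1, 2), (0, 1, 2, 3, 4))
        cov = CoverageMatrix(6, 8)
        assert fitness(b, x, cov, BiclusterConfig()) == pytest.approx(1.3)

    def test_size_reward_decreases_with_size(self):
        cfg = BiclusterConfig()
        a = np.arange(8, dtype=float)
        x = a[:, None] + a[None, :]  # perfectly additive everywhere
        small = fitness(Bicluster((0, 1, 2), (0, 1, 2)), x, cfg=cfg)
        large = fitness(Bicluster((0, 1, 2, 3), (0, 1, 2, 3)), x, cfg=cfg)
        assert large < small

    def test_zero_variance_gets_infinite_sentinel(self):
        x = np.ones((4, 4))
        assert fitness(Bicluster((0, 1), (0, 1)), x) == np.inf

    def test_too_small_gets_infinite_sentinel(self):
        x = np.random.default_rng(0).normal(size=(4, 4))
        assert fitness(Bicluster((0,), (0, 1)), x) == np.inf


def _implant_instance(seed, n=12, m=15, genes=4, conds=5):
    rng = np.random.default_rng(seed + 1000)
    gi = tuple(int(v) for v in rng.choice(n, genes, replace=False))
    cj = tuple(int(v) for v in rng.choice(m, conds, replace=False))
    spec = SyntheticSpec(
        n_genes=n,
        n_conditions=m,
        n_replicates=1,
        replicate_sd=0.0,
        implants=(
            ImplantSpec(
                genes=gi,
                conditions=cj,
                gene_offsets=contrast_offsets(genes, 1.5),
                condition_offsets=contrast_offsets(conds, 1.5),
            ),
        ),
        seed=seed,
    )
    data, _ = generate_dataset(spec)
    return analysis_matrix(data, normalize=False), gi, cj


class TestGaSearch:
    def test_deterministic_given_seed(self):
        x, _, _ = _implant_instance(4)
        assert ga_search(x, seed=99) == ga_search(x, seed=99)

    def test_agrees_with_exhaustive_oracle_on_small_instance(self):
        x, gi, cj = _implant_instance(3, n=8, m=8)
        best, best_fit = exhaustive_search(x)
        found = ga_search(x, seed=0)
        assert found == best
        assert fitness(found, x, CoverageMatrix(8, 8)) == pytest.approx(best_fit)

    def test_noise_matrix_with_tiny_delta_finds_nothing(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(6, 6))
        cfg = BiclusterConfig(delta=1e-6)
        # oracle: no submatrix of this noise matrix is near-additive
        best, _ = exhaustive_search(x, cfg=cfg)
        assert best is None
        assert ga_search(x, cfg=cfg, seed=0) is None

    def test_reported_msr_below_delta(self):
        x, _, _ = _implant_instance(5)
        cfg = BiclusterConfig()
        b = ga_search(x, cfg=cfg, seed=1)
        assert b is not None
        assert mean_squared_residue(b, x) <= cfg.delta


class TestSequentialExtract:
    def test_two_disjoint_implants_recovered_first(self):
        spec = SyntheticSpec(
            n_replicates=1,
            replicate_sd=0.0,
            implants=(
                ImplantSpec(
                    genes=(0, 1, 2, 3),
                    conditions=(0, 1, 2, 3, 4),
                    gene_offsets=contrast_offsets(4, 1.5),
                    condition_offsets=contrast_offsets(5, 1.5),
                ),
                ImplantSpec(
                    genes=(6, 7, 8, 9),
                    conditions=(8, 9, 10, 11, 12),
                    gene_offsets=contrast_offsets(4, 1.5),
                    condition_offsets=contrast_offsets(5, 1.5),
                ),
            ),
            seed=21,
        )
        data, truth = generate_dataset(spec)
        x = analysis_matrix(data, normalize=False)
        found = sequential_extract(x, k=2, seed=5)
        assert len(found) == 2
        truths = [
            (set(range(4)), set(range(5))),
            ({6, 7, 8, 9}, {8, 9, 10, 11, 12}),
        ]
        for tg, tc in truths:
            assert any(
                jaccard(b.rows, tg) >= 0.8 and jaccard(b.cols, tc) >= 0.8 for b in found
            )

    def test_k1_equals_plain_search(self):
        x, _, _ = _implant_instance(6)
        ss = np.random.SeedSequence(7)
        expected = ga_search(x, seed=ss.spawn(1)[0])
        assert sequential_extract(x, k=1, seed=7) == [expected]

    def test_coverage_counts_conserve_volume(self):
        x, _, _ = _implant_instance(7)
        cov = CoverageMatrix(12, 15)
        found = sequential_extract(x, k=3, seed=2, cov=cov)
        assert cov.total() == sum(b.volume for b in found)

    def test_later_rounds_avoid_exact_repeats(self):
        x, _, _ = _implant_instance(9)
        found = sequential_extract(x, k=4, seed=3)
        assert len(set(found)) == len(found)
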