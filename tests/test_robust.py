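"""Bootstrap resampling, pattern counting semantics, grouping, bipartite export."""

import numpy as np
import pytest

from sebic.expression import ReplicatedExpression, analysis_matrix
from sebic.robust import (
    BootstrapEnsemble,
    SubsetPattern,
    bipartite_graph,
    bootstrap_matrix,
    count_patterns,
    group_patterns,
    robust_patterns,
    run_ensemble,
    to_bipartite,
)
from sebic.synthetic import ImplantSpec, SyntheticSpec, contrast_offsets, generate_dataset


def _replicates(values):
    return ReplicatedExpression(("g1", "g2"), ("c1", "c2"), np.asarray(values, dtype=float))


class TestBootstrapMatrix:
    def test_single_replicate_reproduces_mean_matrix(self):
        data = _replicates([[[2.0], [4.0]], [[1.0], [8.0]]])
        x = bootstrap_matrix(data, seed=0, log2=True, normalize=False)
        np.testing.assert_allclose(x.values, np.log2([[2.0, 4.0], [1.0, 8.0]]))

    def test_pseudo_mean_within_replicate_hull(self):
        data = _replicates(
            [[[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]], [[2.0, 2.0, 8.0], [1.0, 3.0, 5.0]]]
        )
        for seed in range(20):
            x = bootstrap_matrix(data, seed=seed, log2=False, normalize=False)
            assert x.values[0, 0] >= 1.0 and x.values[0, 0] <= 3.0
            assert x.values[1, 1] >= 1.0 and x.values[1, 1] <= 5.0

    def test_bootstrap_mean_is_unbiased(self):
        data = _replicates(
            [[[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]], [[2.0, 2.0, 8.0], [1.0, 3.0, 5.0]]]
        )
        mats = np.stack(
            [
                bootstrap_matrix(data, seed=s, log2=False, normalize=False).values
                for s in range(400)
            ]
        )
        np.testing.assert_allclose(
            mats.mean(axis=0), np.nanmean(data.values, axis=2), atol=0.15
        )

    def test_deterministic_given_seed(self):
        data = _replicates(
            [[[1.0, 2.0], [4.0, 5.0]], [[2.0, 8.0], [1.0, 3.0]]]
        )
        a = bootstrap_matrix(data, seed=5, log2=True, normalize=False)
        b = bootstrap_matrix(data, seed=5, log2=True, normalize=False)
        np.testing.assert_array_equal(a.values, b.values)


def _ensemble(per_dataset):
    """Build a label-space ensemble from [(genes, conds), ...] per dataset."""
    rows = tuple(
        tuple((frozenset(g), frozenset(c)) for g, c in biclusters)
        for biclusters in per_dataset
    )
    genes = sorted({g for ds in per_dataset for gs, _ in ds for g in gs})
    conds = sorted({c for ds in per_dataset for _, cs in ds for c in cs})
    return BootstrapEnsemble(tuple(genes), tuple(conds), rows)


class TestCountPatterns:
    def test_direct_counting(self):
        ens = _ensemble(
            [
                [(["a", "b"], ["x", "y"])],
                [(["a", "b", "c"], ["x", "y", "z"])],
                [(["a", "c"], ["x", "z"])],
            ]
        )
        patterns = {(p.genes, p.conditions): p.frequency for p in count_patterns(ens)}
        assert patterns[(frozenset("ab"), frozenset("xy"))] == 2
        assert patterns[(frozenset("ac"), frozenset("xz"))] == 2
        assert patterns[(frozenset("abc"), frozenset("xyz"))] == 1

    def test_counted_once_per_dataset(self):
        # same pattern twice within one dataset still counts once
        ens = _ensemble([[(["a", "b"], ["x", "y"]), (["a", "b"], ["x", "y", "z"])]])
        patterns = {(p.genes, p.conditions): p.frequency for p in count_patterns(ens)}
        assert patterns[(frozenset("ab"), frozenset("xy"))] == 1

    def test_full_bicluster_in_every_dataset_reaches_D(self):
        ens = _ensemble([[(["a", "b"], ["x", "y"])]] * 7)
        patterns = count_patterns(ens)
        assert all(p.frequency <= 7 for p in patterns)
        assert patterns[0].frequency == 7

    def test_anti_monotone(self):
        rng = np.random.default_rng(0)
        per_dataset = []
        genes = list("abcde")
        conds = list("uvwxyz")
        for _ in range(15):
            gs = list(rng.choice(genes, 3, replace=False))
            cs = list(rng.choice(conds, 4, replace=False))
            per_dataset.append([(gs, cs)])
        patterns = count_patterns(_ensemble(per_dataset))
        by_key = {(p.genes, p.conditions): p.frequency for p in patterns}
        for (g, c), freq in by_key.items():
            for (g2, c2), freq2 in by_key.items():
                if g2 <= g and c2 <= c:
                    assert freq2 >= freq

    def test_size_limits_validated(self):
        ens = _ensemble([[(["a", "b"], ["x", "y"])]])
        with pytest.raises(ValueError):
            count_patterns(ens, min_genes=1)


class TestRobustPatterns:
    def test_boundary_just_below_threshold_excluded(self):
        p = SubsetPattern(frozenset("ab"), frozenset("xy"), 499, 1000)
        q = SubsetPattern(frozenset("ab"), frozenset("xz"), 500, 1000)
        kept = robust_patterns([p, q], 1000, threshold_fraction=0.5)
        assert kept == [q]

    def test_maximality_filter(self):
        small = SubsetPattern(frozenset("ab"), frozenset("xy"), 720, 1000)
        large = SubsetPattern(frozenset("ab"), frozenset("xyz"), 700, 1000)
        other = SubsetPattern(frozenset("cd"), frozenset("xy"), 650, 1000)
        kept = robust_patterns([small, large, other], 1000)
        assert large in kept and other in kept and small not in kept


class TestGrouping:
    def test_same_gene_set_merges_with_condition_union(self):
        p1 = SubsetPattern(frozenset({"CER", "HNF6"}), frozenset({"F", "F+W"}), 700, 1000)
        p2 = SubsetPattern(
            frozenset({"CER", "HNF6"}), frozenset({"B+P", "B+P+W"}), 650, 1000
        )
        groups = group_patterns([p1, p2])
        assert len(groups) == 1
        assert groups[0].genes == frozenset({"CER", "HNF6"})
        assert groups[0].conditions == frozenset({"F", "F+W", "B+P", "B+P+W"})

    def test_disjoint_gene_sets_stay_separate(self):
        p1 = SubsetPattern(frozenset("ab"), frozenset("xy"), 700, 1000)
        p2 = SubsetPattern(frozenset("cd"), frozenset("xy"), 650, 1000)
        assert len(group_patterns([p1, p2])) == 2

    def test_order_independent(self):
        ps = [
            SubsetPattern(frozenset("ab"), frozenset("xy"), 700, 1000),
            SubsetPattern(frozenset("ab"), frozenset("yz"), 600, 1000),
            SubsetPattern(frozenset("cd"), frozenset("xy"), 650, 1000),
        ]
        a = group_patterns(ps)
        b = group_patterns(ps[::-1])
        assert {(g.genes, g.conditions) for g in a} == {(g.genes, g.conditions) for g in b}


class TestBipartite:
    def test_complete_block_edge_count(self):
        p = SubsetPattern(frozenset("ab"), frozenset("wxyz"), 700, 1000)
        groups = group_patterns([p])
        edges = to_bipartite(groups)
        assert len(edges) == 8

    def test_empty_groups_empty_edges(self):
        assert to_bipartite([]) == []

    def test_shared_gene_appears_in_both_groups(self):
        p1 = SubsetPattern(frozenset({"CER", "HNF6"}), frozenset({"F", "F+W"}), 700, 1000)
        p2 = SubsetPattern(frozenset({"HNF6", "HNF4A"}), frozenset({"F+B", "F+P"}), 600, 1000)
        groups = group_patterns([p1, p2])
        g = bipartite_graph(groups)
        hnf6_groups = {
            gid for nbr in g.neighbors("HNF6") for gid in g["HNF6"][nbr]["groups"]
        }
        assert len(hnf6_groups) == 2


class TestRunEnsemble:
    def test_noiseless_single_implant_found_in_every_dataset(self):
        spec = SyntheticSpec(
            n_genes=8,
            n_conditions=8,
            n_replicates=2,
            replicate_sd=0.0,
            implants=(
                ImplantSpec(
                    genes=(1, 3, 5, 6),
                    conditions=(0, 2, 4, 6, 7),
                    gene_offsets=contrast_offsets(4, 1.5),
                    condition_offsets=contrast_offsets(5, 1.5),
                ),
            ),
            seed=13,
        )
        data, truth = generate_dataset(spec)
        ens = run_ensemble(data, n_datasets=3, runs_per_dataset=1, seed=5)
        genes, conds = truth.patterns[0]
        for per_dataset in ens.biclusters:
            assert len(per_dataset) == 1
            g, c = per_dataset[0]
            assert g == genes and c == conds

    def test_same_master_seed_identical(self, small_replicates):
        a = run_ensemble(small_replicates, n_datasets=3, runs_per_dataset=1, seed=9)
        b = run_ensemble(small_replicates, n_datasets=3, runs_per_dataset=1, seed=9)
        assert a.biclusters == b.biclusters

    def test_jsonl_round_trip(self, tmp_path, small_replicates):
        ens = run_ensemble(small_replicates, n_datasets=3, runs_per_dataset=1, seed=9)
        path = str(tmp_path / "ens.jsonl")
        ens.to_jsonl(path)
        back = BootstrapEnsemble.from_jsonl(path, ens.gene_ids, ens.condition_ids)
        assert back.biclusters == ens.biclusters
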