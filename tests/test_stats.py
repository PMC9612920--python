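"""Cluster-based permutation machinery against independent oracles."""

import numpy as np
import pytest
import networkx as nx
from scipy import stats as sstats

from mmnadd.simulate import make_layout
from mmnadd.stats import (
    ORDERING_PAIRS,
    TestSpec,
    bonferroni_alpha,
    build_adjacency,
    cluster_stat,
    exhaustive_permutation,
    form_clusters,
    permutation_test,
    samplewise_t,
)


@pytest.fixture(scope="module")
def small_adjacency():
    """Six-pair chain-ish adjacency from a real layout subset."""
    lay = make_layout(24, seed=3)
    idx = [int(i) for i in lay.hemisphere_indices("left")[:6]]
    return build_adjacency(lay, idx)


def brute_force_clusters(t_map, thr, adjacency):
    """Independent connected-components oracle via networkx."""
    found = []
    for sign in (1, -1):
        mask = t_map > thr if sign > 0 else t_map < -thr
        g = nx.Graph()
        nodes = [tuple(x) for x in np.argwhere(mask)]
        g.add_nodes_from(nodes)
        for p, t in nodes:
            if (p, t + 1) in g:
                g.add_edge((p, t), (p, t + 1))
            for q in range(t_map.shape[0]):
                if adjacency.matrix[p, q] and (q, t) in g:
                    g.add_edge((p, t), (q, t))
        for comp in nx.connected_components(g):
            pairs = {p for p, _ in comp}
            ok = any(
                adjacency.matrix[p, q] for p in pairs for q in pairs if p != q
            )
            if ok:
                found.append((sign, frozenset(comp), sum(t_map[p, t] for p, t in comp)))
    return found


class TestBonferroni:
    def test_paper_correction(self):
        assert bonferroni_alpha(0.05, 4) == pytest.approx(0.00625)

    def test_single_comparison(self):
        assert bonferroni_alpha(0.05, 1) == pytest.approx(0.025)

    def test_monotone_in_comparisons(self):
        alphas = [bonferroni_alpha(0.05, n) for n in range(1, 8)]
        assert all(a > b for a, b in zip(alphas, alphas[1:]))


class TestSamplewiseT:
    def test_hand_computed_pooled_t(self):
        a = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        b = np.array([2.0, 3.0, 4.0]).reshape(3, 1, 1)
        t = samplewise_t(a, b, "independent")
        assert t[0, 0] == pytest.approx(-1.2247, abs=1e-4)

    def test_identical_groups_give_zero(self):
        x = np.random.default_rng(0).normal(size=(4, 2, 3))
        assert np.allclose(samplewise_t(x, x.copy(), "independent"), 0.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(5, 2, 3)), rng.normal(size=(6, 2, 3))
        t1 = samplewise_t(a, b, "independent")
        t2 = samplewise_t(a + 10.0, b + 10.0, "independent")
        assert np.allclose(t1, t2)

    def test_matches_scipy_independent(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(8, 3, 4)), rng.normal(size=(6, 3, 4))
        t = samplewise_t(a, b, "independent")
        ref = sstats.ttest_ind(a, b, axis=0, equal_var=True).statistic
        assert np.allclose(t, ref)

    def test_matches_scipy_paired(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(9, 3, 4)), rng.normal(size=(9, 3, 4))
        t = samplewise_t(a, b, "dependent")
        ref = sstats.ttest_rel(a, b, axis=0).statistic
        assert np.allclose(t, ref)

    def test_undersized_designs_rejected(self):
        with pytest.raises(ValueError):
            samplewise_t(np.zeros((1, 2, 2)), np.zeros((3, 2, 2)), "independent")
        with pytest.raises(ValueError):
            samplewise_t(np.zeros((1, 2, 2)), None, "dependent")


class TestAdjacency:
    def test_threshold_below_minimum_distance_errors(self):
        lay = make_layout(24, seed=3)
        idx = [int(i) for i in lay.hemisphere_indices("left")[:6]]
        with pytest.raises(ValueError, match="isolated"):
            build_adjacency(lay, idx, distance_threshold_m=1e-6)

    def test_threshold_above_maximum_gives_complete_graph(self):
        lay = make_layout(24, seed=3)
        idx = [int(i) for i in lay.hemisphere_indices("left")[:6]]
        adj = build_adjacency(lay, idx, distance_threshold_m=1.0)
        assert adj.matrix.sum() == 6 * 5

    def test_matches_brute_force_thresholding(self, small_adjacency):
        lay = make_layout(24, seed=3)
        idx = small_adjacency.pair_indices
        thr = small_adjacency.distance_threshold_m
        d = lay.distances()
        for i_loc, i in enumerate(idx):
            for j_loc, j in enumerate(idx):
                expected = (i != j) and (d[i, j] <= thr)
                assert bool(small_adjacency.matrix[i_loc, j_loc]) == expected

    def test_default_threshold_gives_three_neighbors_mean(self, small_adjacency):
        assert small_adjacency.neighbor_counts().mean() >= 3.0

    def test_symmetric_irreflexive(self, small_adjacency):
        m = small_adjacency.matrix
        assert np.array_equal(m, m.T)
        assert not m.diagonal().any()


class TestFormClusters:
    def test_zero_map_has_no_clusters(self, small_adjacency):
        assert form_clusters(np.zeros((6, 10)), df=10, alpha_forming=0.05,
                             adjacency=small_adjacency) == []

    def test_planted_block_found_with_oracle_membership(self, small_adjacency):
        t_map = np.zeros((6, 10))
        i, j = small_adjacency.edges[0]
        t_map[i, 3:6] = 5.0
        t_map[j, 4:7] = 5.0
        clusters = form_clusters(t_map, 10, 0.05, small_adjacency)
        assert len(clusters) == 1
        thr = sstats.t.ppf(0.975, 10)
        oracle = brute_force_clusters(t_map, thr, small_adjacency)
        assert len(oracle) == 1
        got = frozenset(map(tuple, clusters[0].samples))
        assert got == oracle[0][1]
        assert clusters[0].sum_t == pytest.approx(oracle[0][2])

    def test_single_pair_assembly_discarded(self, small_adjacency):
        t_map = np.zeros((6, 10))
        t_map[2, :] = 6.0
        assert form_clusters(t_map, 10, 0.05, small_adjacency) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_random_grids_match_oracle(self, small_adjacency, seed):
        rng = np.random.default_rng(seed)
        t_map = rng.normal(scale=2.5, size=(6, 10))
        df = 10
        thr = sstats.t.ppf(0.975, df)
        clusters = form_clusters(t_map, df, 0.05, small_adjacency)
        oracle = brute_force_clusters(t_map, thr, small_adjacency)
        got = {(c.sign, frozenset(map(tuple, c.samples))) for c in clusters}
        want = {(s, m) for s, m, _ in oracle}
        assert got == want
        sums = {frozenset(map(tuple, c.samples)): c.sum_t for c in clusters}
        for s, m, total in oracle:
            assert sums[m] == pytest.approx(total)


class TestClusterStat:
    def test_extremes_per_sign(self, small_adjacency):
        t_map = np.zeros((6, 10))
        i, j = small_adjacency.edges[0]
        t_map[i, 1:3] = t_map[j, 1:3] = 4.0
        t_map[i, 6:9] = t_map[j, 6:9] = 5.0
        clusters = form_clusters(t_map, 10, 0.05, small_adjacency)
        stat = cluster_stat(clusters)
        sums = sorted(c.sum_t for c in clusters)
        assert stat["pos"] == pytest.approx(sums[-1])
        assert stat["neg"] is None

    def test_brute_force_recompute(self, small_adjacency):
        rng = np.random.default_rng(5)
        t_map = rng.normal(scale=3, size=(6, 10))
        clusters = form_clusters(t_map, 8, 0.05, small_adjacency)
        for c in clusters:
            assert c.sum_t == pytest.approx(sum(t_map[p, t] for p, t in c.samples))


class TestPermutationTest:
    def test_no_signal_gives_large_p(self, small_adjacency):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 6, 10))
        res = permutation_test(x, x.copy(), TestSpec(design="dependent", n_perm=200, seed=1),
                               small_adjacency)
        assert res.min_p() == 1.0  # identical pairs: no supra-threshold samples

    def test_seeded_reproducibility(self, small_adjacency):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(8, 6, 10)), rng.normal(size=(8, 6, 10))
        spec = TestSpec(design="independent", n_perm=300, seed=5)
        r1 = permutation_test(a, b, spec, small_adjacency)
        r2 = permutation_test(a, b, spec, small_adjacency)
        assert np.array_equal(r1.null_max["pos"], r2.null_max["pos"])
        assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]

    def test_exhaustive_partition_counts(self, small_adjacency):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(3, 6, 10)), rng.normal(size=(3, 6, 10))
        res = exhaustive_permutation(a, b, TestSpec(design="independent", n_perm=100, seed=0),
                                     small_adjacency)
        assert res.n_perm == 20  # C(6,3)

    def test_exhaustive_sign_pattern_counts(self, small_adjacency):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(10, 6, 10)), rng.normal(size=(10, 6, 10))
        res = exhaustive_permutation(a, b, TestSpec(design="dependent", n_perm=100, seed=0),
                                     small_adjacency)
        assert res.n_perm == 1024  # 2**10

    def test_monte_carlo_switches_to_exhaustive_with_warning(self, small_adjacency):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(4, 6, 10)), rng.normal(size=(4, 6, 10))
        with pytest.warns(UserWarning, match="exhaustive"):
            res = permutation_test(a, b, TestSpec(design="independent", n_perm=200, seed=0),
                                   small_adjacency)
        assert res.method == "exhaustive"
        assert res.n_perm == 70  # C(8,4)

    def test_group_relabeling_flips_cluster_signs(self, small_adjacency):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(4, 6, 10))
        b = rng.normal(size=(4, 6, 10)) + 1.5
        spec = TestSpec(design="independent", n_perm=150, seed=2)
        with pytest.warns(UserWarning):
            r_ab = permutation_test(a, b, spec, small_adjacency)
            r_ba = permutation_test(b, a, spec, small_adjacency)
        signs_ab = sorted((c.sign, round(c.sum_t, 9)) for c in r_ab.clusters)
        signs_ba = sorted((-c.sign, round(-c.sum_t, 9)) for c in r_ba.clusters)
        assert signs_ab == signs_ba
        assert r_ab.min_p() == pytest.approx(r_ba.min_p())

    def test_monte_carlo_p_is_never_zero(self, small_adjacency):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(10, 6, 10)) + 3.0
        b = rng.normal(size=(10, 6, 10))
        res = permutation_test(a, b, TestSpec(design="independent", n_perm=250, seed=1),
                               small_adjacency)
        assert res.min_p() >= 1.0 / 251

    def test_channel_reordering_invariance(self, small_adjacency):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(8, 6, 10)); a[:, 1:3, 4:7] += 2.0
        b = rng.normal(size=(8, 6, 10))
        perm = np.array([3, 1, 0, 5, 4, 2])
        adj2 = build_adjacency(
            make_layout(24, seed=3),
            small_adjacency.pair_indices[perm],
            small_adjacency.distance_threshold_m,
        )
        spec = TestSpec(design="dependent", n_perm=200, seed=9)
        r1 = permutation_test(a, b, spec, small_adjacency)
        r2 = permutation_test(a[:, perm], b[:, perm], spec, adj2)
        assert r1.min_p() == pytest.approx(r2.min_p())
        assert r1.observed == pytest.approx(r2.observed)


class TestOrderingPairs:
    def test_nine_listed_comparisons(self):
        assert len(ORDERING_PAIRS) == 9
        assert ("FIL", "FI") in ORDERING_PAIRS and ("LF", "F") in ORDERING_PAIRS
        for larger, smaller in ORDERING_PAIRS:
            assert set(smaller) < set(larger)  # one fewer constituent feature
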