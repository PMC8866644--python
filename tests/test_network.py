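"""Sparsity thresholding, graph metrics against brute-force oracles, and
profile comparison."""

import numpy as np
import pytest

import nirsnet as nn
from nirsnet.errors import NirsnetError
from oracles import brute_clustering, brute_efficiency, random_graph


def _sym(rng, n):
    a = rng.standard_normal((n, n))
    w = np.triu(a, 1) + np.triu(a, 1).T
    np.fill_diagonal(w, np.nan)
    return w


class TestThresholdBySparsity:
    def test_extremes(self):
        rng = np.random.default_rng(0)
        w = _sym(rng, 6)
        assert nn.threshold_by_sparsity(w, 0.0).n_edges == 0
        g1 = nn.threshold_by_sparsity(w, 1.0)
        assert g1.n_edges == 15

    def test_top_pairs_retained(self):
        rng = np.random.default_rng(1)
        w = _sym(rng, 4)
        g = nn.threshold_by_sparsity(w, 0.5)
        iu, ju = np.triu_indices(4, 1)
        order = np.argsort(-w[iu, ju])
        expect = {(iu[k], ju[k]) for k in order[:3]}
        got = {(i, j) for i, j in zip(*np.nonzero(np.triu(g.adjacency, 1)))}
        assert got == expect

    def test_nestedness_across_sparsity(self):
        rng = np.random.default_rng(2)
        w = _sym(rng, 8)
        prev = np.zeros((8, 8), dtype=bool)
        for s in np.linspace(0, 1, 11):
            adj = nn.threshold_by_sparsity(w, s).adjacency
            assert np.all(prev <= adj)
            prev = adj

    def test_absolute_ranking_option(self):
        w = np.array([[np.nan, -5.0, 1.0],
                      [-5.0, np.nan, 0.5],
                      [1.0, 0.5, np.nan]])
        g_signed = nn.threshold_by_sparsity(w, 1 / 3, signed=True)
        g_abs = nn.threshold_by_sparsity(w, 1 / 3, signed=False)
        assert g_signed.adjacency[0, 2] and not g_signed.adjacency[0, 1]
        assert g_abs.adjacency[0, 1] and not g_abs.adjacency[0, 2]

    def test_invalid_sparsity_rejected(self):
        with pytest.raises(NirsnetError):
            nn.threshold_by_sparsity(np.zeros((3, 3)), 1.5)


class TestGraphMetrics:
    def test_triangle_and_path(self):
        tri = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=bool)
        path = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)
        g_tri = nn.BinaryGraph([1, 2, 3], tri, 1.0)
        g_path = nn.BinaryGraph([1, 2, 3], path, 2 / 3)
        assert nn.clustering_coefficient(g_tri) == 1.0
        assert nn.clustering_coefficient(g_path) == 0.0
        assert nn.global_efficiency(g_tri) == 1.0
        assert nn.global_efficiency(g_path) == pytest.approx((1 + 1 + 0.5) / 3)

    def test_metrics_match_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            adj = random_graph(rng, n_max=8)
            g = nn.BinaryGraph(list(range(1, adj.shape[0] + 1)), adj, 0.5)
            assert nn.clustering_coefficient(g) == pytest.approx(
                brute_clustering(adj), abs=1e-12)
            assert nn.global_efficiency(g) == pytest.approx(
                brute_efficiency(adj), abs=1e-12)

    def test_metrics_match_networkx(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(4)
        for _ in range(20):
            adj = random_graph(rng, n_max=8)
            g = nn.BinaryGraph(list(range(1, adj.shape[0] + 1)), adj, 0.5)
            G = nx.from_numpy_array(adj.astype(int))
            assert nn.clustering_coefficient(g) == pytest.approx(
                nx.average_clustering(G), abs=1e-12)
            assert nn.global_efficiency(g) == pytest.approx(
                nx.global_efficiency(G), abs=1e-12)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        adj = random_graph(rng, n_max=8)
        n = adj.shape[0]
        perm = rng.permutation(n)
        adj_p = adj[np.ix_(perm, perm)]
        g = nn.BinaryGraph(list(range(1, n + 1)), adj, 0.5)
        gp = nn.BinaryGraph(list(range(1, n + 1)), adj_p, 0.5)
        assert nn.clustering_coefficient(g) == pytest.approx(
            nn.clustering_coefficient(gp))
        assert nn.global_efficiency(g) == pytest.approx(nn.global_efficiency(gp))


class TestSparsityProfile:
    def test_profile_matches_pointwise_recomputation(self):
        rng = np.random.default_rng(6)
        w = _sym(rng, 13)
        grid = np.linspace(0.05, 1.0, 20)
        prof = nn.sparsity_profile(w, list(range(1, 14)), grid)
        for gi, s in enumerate(grid):
            g = nn.threshold_by_sparsity(w, s)
            assert prof.clustering[gi] == pytest.approx(
                nn.clustering_coefficient(g))
            assert prof.efficiency[gi] == pytest.approx(nn.global_efficiency(g))

    def test_efficiency_nondecreasing_and_saturates(self):
        rng = np.random.default_rng(7)
        w = _sym(rng, 10)
        grid = np.asarray(nn.default_sparsity_grid())
        prof = nn.sparsity_profile(w, list(range(1, 11)), grid)
        assert np.all(np.diff(prof.efficiency) >= -1e-12)
        assert prof.clustering[-1] == 1.0 and prof.efficiency[-1] == 1.0

    def test_hemisphere_subset_is_locally_ranked(self):
        rng = np.random.default_rng(8)
        w = _sym(rng, 10)
        nodes = [2, 4, 6, 8]
        prof = nn.sparsity_profile(w, nodes, np.array([0.5]))
        sub = w[np.ix_([1, 3, 5, 7], [1, 3, 5, 7])]
        g = nn.threshold_by_sparsity(sub, 0.5)
        assert prof.clustering[0] == pytest.approx(nn.clustering_coefficient(g))

    def test_small_hemisphere_rejected(self):
        with pytest.raises(NirsnetError):
            nn.sparsity_profile(np.zeros((5, 5)), [1, 2], np.array([0.5]))


class TestCompareProfiles:
    def test_identical_profiles_no_ranges(self):
        rng = np.random.default_rng(9)
        a = rng.random((5, 30))
        assert nn.compare_profiles(a, a.copy(), np.linspace(0, 1, 30)) == []

    def test_zero_alpha_always_empty(self):
        rng = np.random.default_rng(10)
        a = rng.random((5, 10))
        b = a + 1.0
        assert nn.compare_profiles(a, b, np.linspace(0, 1, 10), alpha=0.0) == []

    def test_shifted_block_detected_with_direction(self):
        rng = np.random.default_rng(11)
        grid = np.linspace(0.1, 1.0, 20)
        a = rng.random((6, 20)) * 0.1
        b = a.copy()
        b[:, 5:10] += 1.0  # all subjects higher over one contiguous run
        ranges = nn.compare_profiles(a, b, grid)
        assert len(ranges) == 1
        r = ranges[0]
        assert r.start == pytest.approx(grid[5])
        assert r.end == pytest.approx(grid[9])
        assert r.direction == 1
        assert 0 < r.p_min <= r.p_max < 0.1

    def test_too_few_subjects_rejected(self):
        a = np.zeros((3, 5))
        with pytest.raises(NirsnetError):
            nn.compare_profiles(a, a, np.linspace(0, 1, 5))
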