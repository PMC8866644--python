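"""Pearson/Fisher-z connectivity, group averaging and strong-edge extraction."""

import numpy as np
import pytest

import nirsnet as nn
from nirsnet.errors import NirsnetError
from nirsnet.synthetic import _psd_sqrt


def _series(data, fs=10.0):
    return nn.HemoTimeSeries(fs, data, np.zeros_like(data))


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert nn.fisher_z(0.0) == 0.0

    def test_unit_z_point(self):
        assert nn.fisher_z(0.76159) == pytest.approx(1.0, abs=1e-4)

    def test_odd_function(self):
        r = np.array([0.1, 0.5, 0.9])
        np.testing.assert_allclose(nn.fisher_z(-r), -np.asarray(nn.fisher_z(r)))

    def test_strictly_increasing_preserves_edge_order(self):
        rng = np.random.default_rng(0)
        r = np.sort(rng.uniform(-0.99, 0.99, 50))
        z = np.asarray(nn.fisher_z(r))
        assert np.all(np.diff(z) > 0)

    def test_saturated_correlation_maps_to_signed_infinity(self):
        assert nn.fisher_z(1.0) == np.inf
        assert nn.fisher_z(-1.0) == -np.inf

    def test_out_of_range_rejected(self):
        with pytest.raises(NirsnetError):
            nn.fisher_z(1.5)


class TestCorrelationMatrix:
    def test_duplicated_channel_gives_unit_r(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500)
        data = np.column_stack([x, x, rng.standard_normal(500)])
        m = nn.correlation_matrix(_series(data))
        assert m.r[0, 1] == pytest.approx(1.0)
        assert np.isnan(m.r[0, 0])  # diagonal masked

    def test_independent_channels_near_zero(self):
        rng = np.random.default_rng(2)
        m = nn.correlation_matrix(_series(rng.standard_normal((10_000, 8))))
        off = m.r[np.triu_indices(8, 1)]
        assert np.abs(off).max() < 0.05

    def test_latent_correlation_recovered(self):
        R = np.eye(4)
        R[0, 1] = R[1, 0] = 0.6
        rng = np.random.default_rng(3)
        data = rng.standard_normal((10_000, 4)) @ _psd_sqrt(R).T
        m = nn.correlation_matrix(_series(data))
        assert m.r[0, 1] == pytest.approx(0.6, abs=0.05)

    def test_zero_variance_channel_undefined(self):
        rng = np.random.default_rng(4)
        data = np.column_stack([rng.standard_normal(100), np.ones(100)])
        m = nn.correlation_matrix(_series(data))
        assert np.isnan(m.r[0, 1])

    def test_task_window_uses_task_samples_only(self, design):
        rng = np.random.default_rng(5)
        n = design.n_samples
        data = rng.standard_normal((n, 3))
        task = design.task_indicator().astype(bool)
        # make a pair perfectly correlated during task blocks only
        data[task, 1] = data[task, 0]
        m = nn.correlation_matrix(_series(data, design.sampling_rate),
                                  window="task_blocks", design=design)
        assert m.r[0, 1] == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(NirsnetError):
            nn.correlation_matrix(_series(np.zeros((10, 3))))


class TestGroupAverage:
    def test_single_matrix_identity(self):
        rng = np.random.default_rng(6)
        r = np.clip((lambda a: (a + a.T) / 2)(rng.uniform(-0.8, 0.8, (4, 4))), -1, 1)
        np.fill_diagonal(r, np.nan)
        m = nn.ConnectivityMatrix(r=r)
        mean_z, counts = nn.group_average([m])
        np.testing.assert_allclose(mean_z[np.isfinite(mean_z)],
                                   m.z[np.isfinite(m.z)])

    def test_opposite_matrices_cancel(self):
        r = np.zeros((3, 3))
        r[0, 1] = r[1, 0] = 0.5
        a = nn.ConnectivityMatrix(r=r)
        b = nn.ConnectivityMatrix(r=-r)
        mean_z, _ = nn.group_average([a, b])
        assert mean_z[0, 1] == pytest.approx(0.0)

    def test_matches_elementwise_mean(self):
        rng = np.random.default_rng(7)
        mats = []
        for _ in range(5):
            a = rng.uniform(-0.8, 0.8, (4, 4))
            r = (a + a.T) / 2
            np.fill_diagonal(r, 0.0)
            mats.append(nn.ConnectivityMatrix(r=r))
        mean_z, counts = nn.group_average(mats)
        brute = np.mean([np.arctanh(m.r) for m in mats], axis=0)
        np.testing.assert_allclose(mean_z, brute)
        assert np.all(counts == 5)

    def test_saturated_entries_excluded_pairwise(self):
        r1 = np.zeros((3, 3)); r1[0, 1] = r1[1, 0] = 1.0   # z = inf
        r2 = np.zeros((3, 3)); r2[0, 1] = r2[1, 0] = 0.5
        mean_z, counts = nn.group_average([nn.ConnectivityMatrix(r=r1),
                                           nn.ConnectivityMatrix(r=r2)])
        assert mean_z[0, 1] == pytest.approx(np.arctanh(0.5))
        assert counts[0, 1] == 1


class TestStrongEdges:
    def test_all_zero_below_threshold(self):
        assert nn.strong_edges(np.zeros((5, 5)), 1.0) == []

    def test_standard_normal_retained_fraction(self):
        rng = np.random.default_rng(8)
        n = 250
        a = rng.standard_normal((n, n))
        z = np.triu(a, 1) + np.triu(a, 1).T
        edges = nn.strong_edges(z, 1.0)
        frac = len(edges) / (n * (n - 1) / 2)
        assert frac == pytest.approx(0.1587, abs=0.012)

    def test_neg_infinite_threshold_returns_all_pairs(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal((6, 6))
        z = np.triu(a, 1) + np.triu(a, 1).T
        assert len(nn.strong_edges(z, -np.inf)) == 15

    def test_sorted_by_descending_z(self):
        z = np.array([[0, 1.5, 2.5], [1.5, 0, 1.2], [2.5, 1.2, 0]])
        edges = nn.strong_edges(z, 1.0)
        assert [e["mean_z"] for e in edges] == sorted(
            (e["mean_z"] for e in edges), reverse=True)
        assert edges[0]["thickness"] == 3

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal((7, 7))
        z = np.triu(a, 1) + np.triu(a, 1).T
        perm = rng.permutation(7)
        zp = z[np.ix_(perm, perm)]
        orig = {frozenset((perm[e["ch_a"] - 1] + 1, perm[e["ch_b"] - 1] + 1))
                for e in nn.strong_edges(zp, 0.5)}
        ref = {frozenset((e["ch_a"], e["ch_b"])) for e in nn.strong_edges(z, 0.5)}
        assert orig == ref
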