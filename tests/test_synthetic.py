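"""Cohort simulator: block timing, latent correlation targets, ground-truth
exactness, seeding contract, MBLL consistency."""

import dataclasses

import numpy as np
import pytest

import nirsnet as nn
from nirsnet.errors import CovarianceError, NirsnetError
from nirsnet.synthetic import LatentModule, _psd_sqrt

FS = 7.8125


class TestMakeDesign:
    def test_default_paradigm_totals_480_seconds(self):
        d = nn.make_design(120, 6, 30, FS)
        assert d.duration_s == 480.0
        assert d.n_samples == int(480 * FS)

    def test_degenerate_design_task_first(self):
        d = nn.make_design(0, 1, 10, 10.0)
        task = d.task_indicator()
        assert np.all(task[:100] == 1.0)
        assert np.all(task[100:] == 0.0)

    def test_task_and_control_tile_post_rest_interval(self):
        d = nn.make_design(120, 6, 30, FS)
        task, ctrl = d.task_indicator(), d.control_indicator()
        assert np.all(task * ctrl == 0)
        post_rest = np.arange(d.n_samples) / FS >= 120
        np.testing.assert_array_equal((task + ctrl).astype(bool), post_rest)

    def test_nonpositive_arguments_rejected(self):
        with pytest.raises(NirsnetError):
            nn.make_design(120, 6, -1, FS)


class TestLatentCovariance:
    def test_single_module_zero_correlation_is_identity(self):
        spec = dataclasses.replace(
            nn.EffectSpec(), r_b=0.0,
            modules=(LatentModule(channels=tuple(range(1, 7)), r_w=0.0),))
        np.testing.assert_array_equal(nn.latent_covariance(spec, 6), np.eye(6))

    def test_two_modules_psd(self):
        spec = dataclasses.replace(
            nn.EffectSpec(), r_b=0.1,
            modules=(LatentModule((1, 2, 3), 0.6), LatentModule((4, 5, 6), 0.6)))
        R = nn.latent_covariance(spec, 6)
        assert np.linalg.eigvalsh(R).min() >= -1e-12
        assert R[0, 1] == 0.6 and R[0, 3] == 0.1
        np.testing.assert_array_equal(np.diag(R), 1.0)

    def test_monte_carlo_sample_correlations_match_targets(self):
        spec = nn.EffectSpec()
        R = nn.latent_covariance(spec, 26)
        rng = np.random.default_rng(4)
        x = rng.standard_normal((10_000, 26)) @ _psd_sqrt(R).T
        sample = np.corrcoef(x, rowvar=False)
        assert np.abs(sample - R).max() < 0.05

    def test_module_outside_channel_range_rejected(self):
        spec = dataclasses.replace(
            nn.EffectSpec(), modules=(LatentModule((1, 99), 0.5),))
        with pytest.raises(CovarianceError):
            nn.latent_covariance(spec, 26)

    def test_overlapping_modules_rejected(self):
        with pytest.raises(CovarianceError):
            dataclasses.replace(
                nn.EffectSpec(),
                modules=(LatentModule((1, 2), 0.5), LatentModule((2, 3), 0.5)))


class TestSimulateSubject:
    def test_zero_noise_oxy_equals_scaled_regressor(self, montage, design,
                                                    quiet_spec):
        truth, _ = nn.simulate_subject(montage, design, quiet_spec, seed=1)
        kernel = nn.canonical_hrf(FS)
        regressor = np.convolve(design.task_indicator(), kernel)[:design.n_samples]
        expected = np.zeros_like(truth.oxy)
        expected[:, 9] = 5e-7 * regressor  # channel 10 active by default
        np.testing.assert_array_equal(truth.oxy, expected)

    def test_null_signal_intensities_constant_at_baseline(self, montage, design,
                                                          quiet_spec):
        spec = dataclasses.replace(quiet_spec, beta={})
        _, raw = nn.simulate_subject(montage, design, spec, seed=1)
        np.testing.assert_array_equal(
            raw.data, np.broadcast_to(raw.baseline, raw.data.shape))

    def test_active_channel_has_max_regressor_correlation(self, montage, design):
        spec = nn.EffectSpec()  # channel 10 active at 0.5 uM
        truth, _ = nn.simulate_subject(montage, design, spec, seed=21)
        kernel = nn.canonical_hrf(FS)
        regressor = np.convolve(design.task_indicator(), kernel)[:design.n_samples]
        corr = [np.corrcoef(truth.oxy[:, c], regressor)[0, 1] for c in range(26)]
        assert int(np.argmax(corr)) == 9

    def test_seeding_contract(self, montage, design):
        spec = nn.EffectSpec()
        _, a = nn.simulate_subject(montage, design, spec, seed=5)
        _, b = nn.simulate_subject(montage, design, spec, seed=5)
        _, c = nn.simulate_subject(montage, design, spec, seed=6)
        np.testing.assert_array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)
        with pytest.raises(NirsnetError):
            nn.simulate_subject(montage, design, spec, seed=None)

    def test_physio_sinusoids_average_out_over_integer_periods(self, montage,
                                                               design, quiet_spec):
        spec = dataclasses.replace(quiet_spec, beta={},
                                   physio=((0.1, 5e-8), (0.25, 5e-8)))
        truth, _ = nn.simulate_subject(montage, design, spec, seed=3)
        # 480 s contains whole periods of both components
        assert np.abs(truth.oxy.mean(axis=0)).max() < 5e-10

    def test_mbll_roundtrip_recovers_truth_noise_free(self, montage, design,
                                                      quiet_spec, optics):
        truth, raw = nn.simulate_subject(montage, design, quiet_spec, seed=2)
        hemo = nn.hemoglobin_from_od(nn.od_from_intensity(raw), optics, FS)
        scale = np.abs(truth.oxy).max()
        assert np.abs(hemo.oxy - truth.oxy).max() / scale < 1e-8
        assert np.abs(hemo.deoxy - truth.deoxy).max() / scale < 1e-8


class TestSimulateCohort:
    def test_shapes_and_sessions(self, montage):
        cohort = nn.simulate_cohort(2, ["T0", "T1", "T2"], seed=7)
        assert len(cohort.recordings) == 6
        for rec in cohort.recordings:
            assert rec.raw.data.shape == (int(480 * FS), 26, 2)
        assert cohort.sessions == ["T0", "T1", "T2"]

    def test_unknown_session_rejected(self):
        with pytest.raises(NirsnetError):
            nn.simulate_cohort(2, ["T0", "T9"], seed=7)

    def test_session_override_changes_latent_structure(self, montage):
        base = nn.EffectSpec()
        raised = base.with_hemisphere_rw(montage, "left", 0.5)
        cohort = nn.simulate_cohort(1, ["T0", "T1"], spec=base,
                                    session_overrides={"T1": raised}, seed=8)
        r0 = cohort.get(1, "T0").latent_correlation
        r1 = cohort.get(1, "T1").latent_correlation
        assert r0[0, 1] == pytest.approx(0.15)
        assert r1[0, 1] == pytest.approx(0.5)
        assert r1[13, 14] == pytest.approx(0.15)  # right hemisphere untouched

    def test_master_seed_determinism(self):
        a = nn.simulate_cohort(2, ["T0"], seed=9)
        b = nn.simulate_cohort(2, ["T0"], seed=9)
        np.testing.assert_array_equal(a.recordings[1].raw.data,
                                      b.recordings[1].raw.data)
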