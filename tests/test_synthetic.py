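"""fGn generator exactness and synthetic-trial structure/ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitprint import (
    FgnSpec,
    TrialConfig,
    fgn_autocorrelation,
    simulate_fgn,
    simulate_trial,
)
from gaitprint.errors import AnalysisError, GenerationError


class TestFgnAutocorrelation:
    def test_closed_form_values(self):
        assert fgn_autocorrelation(0.5, 1) == pytest.approx(0.0, abs=1e-15)
        assert fgn_autocorrelation(1.0, 1) == pytest.approx(1.0)
        # 1/2 (2^1.8 - 2), evaluated independently
        assert fgn_autocorrelation(0.9, 1) == pytest.approx(0.7411011265922482)
        assert fgn_autocorrelation(0.3, 0) == 1.0

    def test_domain_errors(self):
        with pytest.raises(AnalysisError):
            fgn_autocorrelation(0.0, 1)
        with pytest.raises(AnalysisError):
            fgn_autocorrelation(1.2, 1)
        with pytest.raises(AnalysisError):
            fgn_autocorrelation(0.5, -1)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(h=st.floats(0.05, 1.0), k=st.integers(0, 500))
    def test_bounds(self, h, k):
        rho = fgn_autocorrelation(h, k)
        assert -0.5 - 1e-12 <= rho <= 1.0 + 1e-12
        assert fgn_autocorrelation(h, 0) == 1.0


class TestSimulateFgn:
    def test_deterministic_given_seed(self):
        a = simulate_fgn(FgnSpec(0.7, 512, seed=42))
        b = simulate_fgn(FgnSpec(0.7, 512, seed=42))
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("h,tol", [(0.5, 0.01), (0.9, 0.02)])
    def test_lag1_autocorrelation_matches_theory(self, h, tol):
        """Monte-Carlo pooled lag-1 autocovariance vs the closed form."""
        num = den = 0.0
        for s in range(200):
            x = simulate_fgn(FgnSpec(h, 2048, seed=s))
            num += x[1:] @ x[:-1]
            den += x @ x
        assert num / den == pytest.approx(fgn_autocorrelation(h, 1), abs=tol)

    def test_sigma_scales_series(self):
        a = simulate_fgn(FgnSpec(0.8, 256, sigma=1.0, seed=1))
        b = simulate_fgn(FgnSpec(0.8, 256, sigma=2.5, seed=1))
        np.testing.assert_allclose(b, 2.5 * a)

    def test_invalid_spec_rejected(self):
        for kwargs in ({"h": 0.0, "n": 64}, {"h": 0.5, "n": 1},
                       {"h": 0.5, "n": 64, "sigma": 0.0}):
            with pytest.raises(AnalysisError):
                FgnSpec(**kwargs)


class TestSimulateTrial:
    def test_standard_shape(self, standard_trial):
        trial, _ = standard_trial
        assert trial.n_samples == 48_000
        assert trial.channels.shape == (48_000, 320)
        assert trial.fs == pytest.approx(200.0)

    def test_truth_events_consistent(self, standard_trial):
        _, truth = standard_trial
        np.testing.assert_allclose(np.diff(truth.hs_r), truth.stride_times_r)
        assert np.all(np.diff(truth.hs_r) > 0)
        assert np.all(np.diff(truth.hs_l) > 0)
        # ~218 strides in 240 s at 1.1 s mean stride time
        assert truth.hs_r.size == pytest.approx(219, abs=2)

    def test_stride_stats_match_config(self):
        cfg = TrialConfig(seed=21)
        _, truth = simulate_trial(cfg)
        n = truth.stride_times_r.size
        assert truth.stride_times_r.mean() == pytest.approx(
            cfg.mean_stride_time, abs=4 * cfg.stride_time_sd / np.sqrt(n) * 3)
        assert truth.stride_times_r.std() == pytest.approx(
            cfg.stride_time_sd, rel=0.5)
        assert truth.stride_lengths_r.mean() == pytest.approx(
            cfg.mean_stride_length, rel=0.02)

    def test_antiphase_interleaving(self, standard_trial):
        """With 0.5 cycle offset, left heel strikes bisect right strides."""
        _, truth = standard_trial
        for hs_l in truth.hs_l[1:-1]:
            k = np.searchsorted(truth.hs_r, hs_l)
            if 0 < k < truth.hs_r.size:
                frac = (hs_l - truth.hs_r[k - 1]) / \
                    (truth.hs_r[k] - truth.hs_r[k - 1])
                assert frac == pytest.approx(0.5, abs=0.05)

    def test_drift_displaces_horizontal_only(self, channel_map):
        rate, dur = 0.01, 30.0
        base, _ = simulate_trial(TrialConfig(duration_s=dur, seed=3))
        drifted, truth = simulate_trial(
            TrialConfig(duration_s=dur, drift_rate=rate, drift_azimuth_deg=90.0,
                        seed=3))
        dy = (drifted.role(channel_map, "pelvis_pos_y")
              - base.role(channel_map, "pelvis_pos_y"))
        dz = (drifted.role(channel_map, "pelvis_pos_z")
              - base.role(channel_map, "pelvis_pos_z"))
        assert dy[-1] == pytest.approx(rate * (dur - 1.0 / 200.0), rel=1e-6)
        np.testing.assert_array_equal(dz, 0.0)
        assert truth.drift_rate == rate

    def test_bad_parameters_raise(self):
        with pytest.raises(GenerationError):
            TrialConfig(duration_s=240.001, fs=200.0)  # non-integer samples
        with pytest.raises(GenerationError):
            TrialConfig(mean_stride_time=0.3)
        with pytest.raises(GenerationError):
            # Fluctuations larger than the mean produce non-positive strides.
            simulate_trial(TrialConfig(stride_time_sd=1.0, seed=0))
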