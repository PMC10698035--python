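"""Event detection against ground truth and gait-parameter recovery."""

import numpy as np
import pytest

from gaitprint import (
    RawTrial,
    TrialConfig,
    compute_gait_parameters,
    detect_gait_events,
    simulate_trial,
    standard_channel_names,
    summarize_trial,
)
from gaitprint.core_io import GaitParameterTable
from gaitprint.errors import AnalysisError, InsufficientDataError
from gaitprint.events import GaitEvents, _point_line_distance


def _match_errors(detected, truth):
    """Distance (s) from each detected event to the nearest true event."""
    return np.array([np.min(np.abs(truth - t)) for t in detected])


@pytest.fixture(scope="module")
def extracted(standard_trial, standard_events, channel_map):
    trial, truth = standard_trial
    table = compute_gait_parameters(standard_events, trial, channel_map)
    return trial, truth, standard_events, table


class TestDetection:
    def test_events_within_one_sample_of_truth(self, extracted):
        trial, truth, events, _ = extracted
        dt = 1.0 / trial.fs
        for det, tru in ((events.hs_r, truth.hs_r), (events.hs_l, truth.hs_l),
                         (events.to_r, truth.to_r), (events.to_l, truth.to_l)):
            assert _match_errors(det, tru).max() <= dt + 1e-12

    def test_stride_count_matches_duration(self, extracted):
        _, truth, events, _ = extracted
        # 240 s at ~1.1 s per stride, minus boundary footfalls
        assert events.hs_r.size == pytest.approx(218, abs=3)
        assert abs(events.hs_r.size - truth.hs_r.size) <= 2

    def test_alternation_invariant(self, extracted):
        _, _, events, _ = extracted
        for side in ("l", "r"):
            hs = getattr(events, f"hs_{side}")
            to = getattr(events, f"to_{side}")
            assert np.all(to > hs)            # stance positive
            assert np.all(hs[1:] > to[:-1])   # swing positive

    def test_constant_channels_rejected(self, channel_map):
        names = standard_channel_names()
        trial = RawTrial(time_ms=np.arange(4000) * 5.0,
                         channels=np.zeros((4000, len(names))),
                         channel_names=names)
        with pytest.raises(InsufficientDataError):
            detect_gait_events(trial, channel_map)

    def test_unpaired_events_rejected(self):
        with pytest.raises(AnalysisError):
            GaitEvents(hs_l=np.array([0.0, 1.0]), to_l=np.array([0.6]),
                       hs_r=np.array([0.5]), to_r=np.array([1.1]))


class TestParameters:
    def test_stride_time_definition(self, extracted):
        _, _, events, table = extracted
        np.testing.assert_allclose(table.column("right stride time (s)"),
                                   np.diff(events.hs_r), atol=1e-12)

    def test_cadence_definition(self, extracted):
        _, _, _, table = extracted
        step = table.column("step time (s)")
        np.testing.assert_allclose(table.column("cadence (steps/min)"),
                                   60.0 / step, atol=1e-9)

    def test_step_width_point_line_geometry(self):
        # Heel centers L=(0,0), R=(0.60,0.12), next L=(1.20,0):
        # right step width is the point-to-line distance, 12 cm.
        p = np.array([0.60, 0.12])
        a, b = np.array([0.0, 0.0]), np.array([1.20, 0.0])
        assert _point_line_distance(p, a, b) == pytest.approx(0.12)
        # brute-force oracle: minimum distance to densely sampled line
        ts = np.linspace(-5, 5, 200001)
        pts = a[None, :] + ts[:, None] * (b - a)[None, :]
        brute = np.min(np.hypot(*(pts - p).T))
        assert _point_line_distance(p, a, b) == pytest.approx(brute, abs=1e-6)

    def test_parameter_recovery_within_1pct(self, extracted):
        _, truth, _, table = extracted
        checks = {
            "right stride time (s)": truth.stride_times_r.mean(),
            "left stride time (s)": truth.stride_times_l.mean(),
            "right stride length (cm)": truth.stride_lengths_r.mean() * 100,
            "left stride length (cm)": truth.stride_lengths_l.mean() * 100,
            "left step width (cm)": truth.step_width * 100,
            "right step width (cm)": truth.step_width * 100,
            "average speed (m/s)": truth.mean_speed,
        }
        for col, expected in checks.items():
            assert table.column(col).mean() == pytest.approx(expected, rel=0.01), col

    def test_single_support_equals_contralateral_swing(self, extracted):
        trial, _, events, table = extracted
        dt = 1.0 / trial.fs
        single = table.column("single support time (s)")
        swing_l = table.column("left swing time (s)")
        # one value per right-reference cycle; the matching left swing may be
        # indexed one off depending on which foot struck first
        n = min(single.size, swing_l.size) - 2
        errs = [np.max(np.abs(single[1:n] - swing_l[1 + off:n + off]))
                for off in (-1, 0, 1)]
        assert min(errs) <= 2 * dt

    def test_speed_times_time_equals_distance(self, extracted):
        trial, _, _, table = extracted
        speed = table.column("average speed (m/s)")[0]
        dist = table.column("distance traveled (m)")[0]
        assert speed * trial.duration_s == pytest.approx(dist, rel=0.005)

    def test_step_counts_balanced(self, extracted):
        _, _, events, _ = extracted
        assert abs(events.hs_l.size - events.hs_r.size) <= 1


class TestSummaries:
    def test_summary_recovers_truth(self, extracted):
        _, truth, _, table = extracted
        summary = summarize_trial(table).set_index("parameter")
        assert summary.loc["right stride time (s)", "mean"] == pytest.approx(
            truth.stride_times_r.mean(), rel=0.01)
        assert summary.loc["right stride length (cm)", "mean"] == pytest.approx(
            truth.stride_lengths_r.mean() * 100, rel=0.01)

    def test_constant_column_zero_sd(self, extracted):
        _, _, _, table = extracted
        df = table.data.copy()
        df["left stride time (s)"] = 1.2
        summary = summarize_trial(
            GaitParameterTable(data=df, key=table.key)).set_index("parameter")
        assert summary.loc["left stride time (s)", "mean"] == pytest.approx(1.2)
        assert summary.loc["left stride time (s)", "sd"] == pytest.approx(0.0)

    def test_empty_table_rejected(self):
        import pandas as pd
        from gaitprint import GAIT_TABLE_COLUMNS
        empty = GaitParameterTable(
            data=pd.DataFrame({c: [] for c in GAIT_TABLE_COLUMNS}))
        with pytest.raises(AnalysisError):
            summarize_trial(empty)
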