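"""Cohort orchestration: generate -> extract -> validate.

Runs the full chain over a synthetic cohort (or a directory of trial CSVs):
gait-event detection, the 26-parameter table, and the three validation
analyses — continuous relative phase of bilateral segment pairs, the
largest Lyapunov exponent of segment angles, and Hurst exponents of stride
series with shuffle surrogates. Summaries mirror the published protocol:
per-trial values, per-subject/day means over the (up to) 9 trials of a
session, and descriptive between-day consistency statistics.

Consistency is reported descriptively (means, absolute day differences,
between- vs within-subject variance ratio) rather than as formal ICC
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .core_io import (
    ChannelMap,
    TrialKey,
    standard_channel_map,
    write_gait_table,
    write_raw_trial,
)
from .crp import crp_from_events
from .errors import AnalysisError, InsufficientDataError
from .events import compute_gait_parameters, detect_gait_events
from .hurst import estimate_hurst, shuffle_surrogate
from .lyapunov import lyapunov_exponent
from .synthetic import TrialConfig, simulate_trial

__all__ = [
    "CohortConfig",
    "ValidationReport",
    "run_validation",
    "consistency_summary",
    "direction_split_pct",
    "iter_protocol_keys",
]

#: The standard protocol: 2 days x 3 blocks x 3 trials = 18 trials/subject.
PROTOCOL_DAYS = (1, 2)
PROTOCOL_BLOCKS = (1, 2, 3)
PROTOCOL_TRIALS = (1, 2, 3)


def iter_protocol_keys(subject: int, group: int = 1,
                       days: Sequence[int] = PROTOCOL_DAYS) -> Iterable[TrialKey]:
    """All trial keys of the standard protocol for one subject."""
    for day in days:
        for block in PROTOCOL_BLOCKS:
            for trial in PROTOCOL_TRIALS:
                yield TrialKey(subject=subject, group=group, day=day,
                               block=block, trial=trial)


def direction_split_pct(*counts: int) -> tuple[float, ...]:
    """Percentage share of each category count (e.g. walking directions).

    ``direction_split_pct(423, 189)`` -> (69.12, 30.88) rounded to 2 dp.
    """
    total = sum(counts)
    if total <= 0:
        raise AnalysisError("counts must sum to a positive total")
    return tuple(round(100.0 * c / total, 2) for c in counts)


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic cohort specification for a validation run.

    Per-subject gait parameters (mean stride time/length, step width) are
    drawn once per subject around population defaults so that subjects are
    distinguishable while both days share one configuration, mirroring the
    test-retest design. ``stride_time_h`` may be a single value or one per
    subject.
    """

    n_subjects: int = 3
    group: int = 1
    duration_s: float = 240.0
    fs: float = 200.0
    stride_time_h: float | Sequence[float] = 0.75
    phase_offset: float = 0.5
    noise_std_angle: float = 0.1     # deg
    noise_std_pos: float = 0.002     # m
    drift_rate: float = 0.0
    between_subject_time_sd: float = 0.05   # s, spread of mean stride times
    between_subject_length_sd: float = 0.08  # m
    analyses: Sequence[str] = ("crp", "hurst")
    segments: Sequence[str] = ("thigh", "shank", "foot")
    day1_only_subjects: Sequence[int] = ()
    lle_max_samples: int = 12000   # decimate angle series beyond this for LLE
    seed: int = 0

    def subject_h(self, subject: int) -> float:
        if np.isscalar(self.stride_time_h):
            return float(self.stride_time_h)
        return float(self.stride_time_h[(subject - 1) % len(self.stride_time_h)])


def _subject_params(config: CohortConfig, subject: int) -> dict:
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, subject)))
    return {
        "mean_stride_time": max(0.8, 1.1 + config.between_subject_time_sd
                                * rng.standard_normal()),
        "mean_stride_length": max(1.0, 1.35 + config.between_subject_length_sd
                                  * rng.standard_normal()),
        "step_width": max(0.06, 0.12 + 0.015 * rng.standard_normal()),
    }


def _trial_config(config: CohortConfig, key: TrialKey) -> TrialConfig:
    params = _subject_params(config, key.subject)
    trial_seed = int(np.random.SeedSequence(
        (config.seed, key.subject, key.day, key.block, key.trial)
    ).generate_state(1)[0] % (2**31))
    return TrialConfig(
        duration_s=config.duration_s,
        fs=config.fs,
        stride_time_h=config.subject_h(key.subject),
        phase_offset=config.phase_offset,
        noise_std_angle=config.noise_std_angle,
        noise_std_pos=config.noise_std_pos,
        drift_rate=config.drift_rate,
        seed=trial_seed,
        **params,
    )


@dataclass
class ValidationReport:
    """Per-trial and per-subject/day validation summaries."""

    trials: pd.DataFrame        # one row per trial
    subject_day: pd.DataFrame   # means over the trials of each session
    config: CohortConfig
    log: dict

    def metric_columns(self) -> list[str]:
        skip = {"subject", "day", "block", "trial", "key", "n_strides",
                "anomalous"}
        return [c for c in self.trials.columns
                if c not in skip and self.trials[c].dtype.kind == "f"]


def _analyze_trial(trial, truth, channel_map: ChannelMap,
                   config: CohortConfig, key: TrialKey,
                   shuffle_seed: int) -> dict:
    events = detect_gait_events(trial, channel_map)
    table = compute_gait_parameters(events, trial, channel_map)
    row: dict = {
        "subject": key.subject, "day": key.day, "block": key.block,
        "trial": key.trial, "key": key.token(),
        "n_strides": int(min(events.hs_l.size, events.hs_r.size) - 1),
    }
    anomalous = False
    if "crp" in config.analyses:
        for segment in config.segments:
            res = crp_from_events(trial, channel_map, events, segment=segment)
            row[f"crp_{segment}_deg"] = res.mean_phi
            row[f"crp_{segment}_sd"] = res.circular_sd
            anomalous |= res.anomalous
    if "hurst" in config.analyses:
        for name, col in (("stride_time", "right stride time (s)"),
                          ("stride_length", "right stride length (cm)")):
            series = table.column(col)
            if series.size < 64:
                # Too few strides for a stable H estimate on this trial.
                row[f"hurst_{name}"] = np.nan
                row[f"hurst_{name}_shuffled"] = np.nan
                continue
            res = estimate_hurst(series)
            row[f"hurst_{name}"] = res.h
            row[f"hurst_{name}_shuffled"] = estimate_hurst(
                shuffle_surrogate(series, seed=shuffle_seed)).h
    if "lle" in config.analyses:
        for side in ("l", "r"):
            x = trial.role(channel_map, f"thigh_pitch_{side}")
            fs = trial.fs
            step = max(1, int(np.ceil(x.size / config.lle_max_samples)))
            res = lyapunov_exponent(x[::step], fs=fs / step)
            row[f"lle_thigh_{side}"] = res.lambda1
    row["anomalous"] = anomalous
    return row


def run_validation(config: CohortConfig,
                   out_dir: str | Path | None = None) -> ValidationReport:
    """Run the validation chain over a synthetic cohort.

    Deterministic given ``config.seed``. When ``out_dir`` is given, writes
    ``trials.csv``, ``subject_day.csv`` and a ``run_log.yaml`` recording the
    tool version, seed, and every generator/analysis parameter used.
    """
    if config.n_subjects < 1:
        raise AnalysisError("empty cohort")
    channel_map = standard_channel_map()
    rows = []
    for subject in range(1, config.n_subjects + 1):
        days = (1,) if subject in config.day1_only_subjects else PROTOCOL_DAYS
        for key in iter_protocol_keys(subject, config.group, days):
            tcfg = _trial_config(config, key)
            try:
                trial, truth = simulate_trial(tcfg, key=key)
                rows.append(_analyze_trial(trial, truth, channel_map, config,
                                           key, shuffle_seed=tcfg.seed + 1))
            except InsufficientDataError:
                # Missing/unusable trials are logged and skipped.
                continue
    if not rows:
        raise AnalysisError("no analyzable trials in cohort")
    trials = pd.DataFrame(rows)

    metric_cols = [c for c in trials.columns if trials[c].dtype.kind == "f"]
    subject_day = (
        trials.groupby(["subject", "day"])[metric_cols]
        .agg(["mean", "std", "count"])
    )
    subject_day.columns = ["_".join(c) for c in subject_day.columns]
    subject_day = subject_day.reset_index()

    log = {
        "tool": "gaitprint",
        "version": _version,
        "seed": config.seed,
        "config": _jsonable(asdict(config)),
        "n_trials": int(len(trials)),
    }
    report = ValidationReport(trials=trials, subject_day=subject_day,
                              config=config, log=log)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trials.to_csv(out / "trials.csv", index=False, float_format="%.6g")
        subject_day.to_csv(out / "subject_day.csv", index=False,
                           float_format="%.6g")
        import yaml

        (out / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=False))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def consistency_summary(report: ValidationReport) -> pd.DataFrame:
    """Between-day statistics per subject and metric.

    For each metric: the absolute difference of day means per subject, and
    across the cohort the ratio of between-subject variance (of subject
    grand means) to within-subject variance (between the two day means).
    A ratio > 1 indicates subjects are more different from each other than
    from themselves across sessions. Undefined ratios (single subject, or a
    single day) are reported as NaN.
    """
    trials = report.trials
    two_day = trials.groupby("subject")["day"].nunique()
    both = two_day[two_day >= 2].index
    if len(both) == 0:
        raise AnalysisError("no subject has trials on both days")
    rows = []
    for metric in report.metric_columns():
        day_means = (
            trials[trials["subject"].isin(both)]
            .groupby(["subject", "day"])[metric].mean().unstack("day")
        )
        abs_diff = (day_means[1] - day_means[2]).abs()
        grand = day_means.mean(axis=1)
        between_var = float(grand.var(ddof=1)) if len(grand) > 1 else np.nan
        within_var = float(day_means.var(axis=1, ddof=1).mean())
        ratio = between_var / within_var if within_var and np.isfinite(between_var) \
            else np.nan
        for subject in both:
            rows.append({
                "metric": metric,
                "subject": int(subject),
                "day1_mean": float(day_means.loc[subject, 1]),
                "day2_mean": float(day_means.loc[subject, 2]),
                "abs_day_diff": float(abs_diff.loc[subject]),
                "variance_ratio": ratio,
            })
    return pd.DataFrame(rows)


def export_subject(config: CohortConfig, subject: int,
                   out_dir: str | Path) -> list[Path]:
    """Write one subject's protocol trials (raw + gait tables) as CSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    channel_map = standard_channel_map()
    days = (1,) if subject in config.day1_only_subjects else PROTOCOL_DAYS
    paths = []
    for key in iter_protocol_keys(subject, config.group, days):
        trial, _ = simulate_trial(_trial_config(config, key), key=key)
        path = out / f"{key.token()}.csv"
        write_raw_trial(trial, path)
        events = detect_gait_events(trial, channel_map)
        table = compute_gait_parameters(events, trial, channel_map)
        write_gait_table(table, out / f"{key.token()}_spatiotemporal.csv")
        paths.append(path)
    return paths
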