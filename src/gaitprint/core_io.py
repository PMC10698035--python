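"""Trial identity, raw-trial data model, and CSV readers/writers.

A raw overground-walking trial is a time-stamped multichannel kinematic
matrix: a ``Time`` column in milliseconds followed by 320 named kinematic
channels sampled at 200 Hz, 48,000 rows for a standard four-minute trial.
Spatiotemporal gait parameters are stored as a fixed 26-column table, one
row per step/stride sample, with shorter series padded with empty cells.

Positions are carried in meters internally (right-handed frame: x =
direction of progression, y = lateral, z = vertical) and converted to the
published units (cm) only at the gait-table boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError, TrialIdError

__all__ = [
    "TrialKey",
    "RawTrial",
    "ChannelMap",
    "GaitParameterTable",
    "GAIT_TABLE_COLUMNS",
    "CHANNEL_ROLES",
    "parse_trial_id",
    "standard_channel_names",
    "standard_channel_map",
    "read_raw_trial",
    "write_raw_trial",
    "read_gait_table",
    "write_gait_table",
]

#: Number of kinematic channels in a standard raw export (total columns = 321
#: including the leading ``Time`` column).
N_CHANNELS = 320

#: Standard sampling rate of the IMU export, Hz.
STANDARD_FS = 200.0

#: Semantic channel roles the analysis pipeline can request.
CHANNEL_ROLES = (
    "thigh_pitch_l", "thigh_pitch_r",
    "shank_pitch_l", "shank_pitch_r",
    "foot_pitch_l", "foot_pitch_r",
    "foot_gyro_pitch_l", "foot_gyro_pitch_r",
    "foot_pos_x_l", "foot_pos_y_l", "foot_pos_z_l",
    "foot_pos_x_r", "foot_pos_y_r", "foot_pos_z_r",
    "pelvis_pos_x", "pelvis_pos_y", "pelvis_pos_z",
)

_ROLE_COLUMNS = {
    "thigh_pitch_l": "Lt Thigh Pitch (deg)",
    "thigh_pitch_r": "Rt Thigh Pitch (deg)",
    "shank_pitch_l": "Lt Shank Pitch (deg)",
    "shank_pitch_r": "Rt Shank Pitch (deg)",
    "foot_pitch_l": "Lt Foot Pitch (deg)",
    "foot_pitch_r": "Rt Foot Pitch (deg)",
    "foot_gyro_pitch_l": "Lt Foot Gyro Pitch (deg/s)",
    "foot_gyro_pitch_r": "Rt Foot Gyro Pitch (deg/s)",
    "foot_pos_x_l": "Lt Foot Position X (m)",
    "foot_pos_y_l": "Lt Foot Position Y (m)",
    "foot_pos_z_l": "Lt Foot Position Z (m)",
    "foot_pos_x_r": "Rt Foot Position X (m)",
    "foot_pos_y_r": "Rt Foot Position Y (m)",
    "foot_pos_z_r": "Rt Foot Position Z (m)",
    "pelvis_pos_x": "Pelvis Position X (m)",
    "pelvis_pos_y": "Pelvis Position Y (m)",
    "pelvis_pos_z": "Pelvis Position Z (m)",
}

#: Column order of the published spatiotemporal table (exactly 26 columns).
GAIT_TABLE_COLUMNS = (
    "cadence (steps/min)",
    "step time (s)",
    "left step length (cm)",
    "right step length (cm)",
    "left step width (cm)",
    "right step width (cm)",
    "left stride length (cm)",
    "right stride length (cm)",
    "left stride time (s)",
    "right stride time (s)",
    "left stance time (s)",
    "right stance time (s)",
    "left swing time (s)",
    "right swing time (s)",
    "single support time (s)",
    "double support time (s)",
    "left pct stance (%GC)",
    "right pct stance (%GC)",
    "left pct swing (%GC)",
    "right pct swing (%GC)",
    "pct single (%GC)",
    "pct double (%GC)",
    "average speed (m/s)",
    "left stride speed (m/s)",
    "right stride speed (m/s)",
    "distance traveled (m)",
)

_TOKEN_SEGMENTS = (
    ("S", "subject", 3, 1, 999),
    ("G", "group", 2, 1, 99),
    ("D", "day", 2, 1, 2),
    ("B", "block", 2, 1, 3),
    ("T", "trial", 2, 1, 3),
)


@dataclass(frozen=True, order=True)
class TrialKey:
    """Identity of one trial: subject, group, day, block, trial.

    Renders to / parses from the canonical token ``S###_G##_D##_B##_T##``.
    """

    subject: int
    group: int = 1
    day: int = 1
    block: int = 1
    trial: int = 1

    def __post_init__(self) -> None:
        for prefix, name, _, lo, hi in _TOKEN_SEGMENTS:
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or not lo <= value <= hi:
                raise TrialIdError(
                    f"{name} must be an integer in [{lo}, {hi}], got {value!r}"
                )

    def token(self) -> str:
        return (
            f"S{self.subject:03d}_G{self.group:02d}_D{self.day:02d}"
            f"_B{self.block:02d}_T{self.trial:02d}"
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token()


def parse_trial_id(token: str) -> TrialKey:
    """Parse a trial token like ``S001_G01_D01_B01_T01`` into a :class:`TrialKey`.

    Raises :class:`TrialIdError` naming the offending segment on malformed
    input (wrong segment count, bad prefix, non-numeric, out of range).
    """
    if not token:
        raise TrialIdError("empty trial token")
    parts = token.split("_")
    if len(parts) != len(_TOKEN_SEGMENTS):
        expected = "_".join(p for p, *_ in _TOKEN_SEGMENTS)
        raise TrialIdError(
            f"expected 5 segments ({expected}##...), got {len(parts)} in {token!r}"
        )
    values = {}
    for part, (prefix, name, width, lo, hi) in zip(parts, _TOKEN_SEGMENTS):
        if not re.fullmatch(rf"{prefix}\d{{{width},}}", part):
            raise TrialIdError(f"segment {part!r} is not a valid {name} field")
        value = int(part[1:])
        if not lo <= value <= hi:
            raise TrialIdError(
                f"segment {part!r}: {name} out of range [{lo}, {hi}]"
            )
        values[name] = value
    return TrialKey(**values)


def standard_channel_names() -> list[str]:
    """The 320 kinematic channel names of the synthetic export schema.

    The roles the pipeline consumes carry explicit names; the remainder are
    placeholder channels so the total matches the published 321-column shape.
    """
    named = list(_ROLE_COLUMNS.values())
    n_aux = N_CHANNELS - len(named)
    return named + [f"Aux {i:03d}" for i in range(1, n_aux + 1)]


@dataclass(frozen=True)
class ChannelMap:
    """Mapping from semantic channel roles to raw-trial column names."""

    roles: Mapping[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.roles) - set(CHANNEL_ROLES)
        if unknown:
            raise SchemaError(f"unknown channel roles: {sorted(unknown)}")

    def column(self, role: str) -> str:
        if role not in self.roles:
            raise SchemaError(f"channel map does not define role {role!r}")
        return self.roles[role]

    def validate(self, trial: "RawTrial", required: Iterable[str] | None = None) -> None:
        """Check that every (required) role resolves to an existing column."""
        wanted = list(required) if required is not None else list(self.roles)
        missing_roles = [r for r in wanted if r not in self.roles]
        if missing_roles:
            raise SchemaError(f"channel map missing roles: {missing_roles}")
        cols = set(trial.channel_names)
        absent = [r for r in wanted if self.roles[r] not in cols]
        if absent:
            raise SchemaError(
                "mapped columns absent from trial for roles: "
                + ", ".join(f"{r} -> {self.roles[r]!r}" for r in absent)
            )


def standard_channel_map() -> ChannelMap:
    """Channel map for the synthetic export schema."""
    return ChannelMap(dict(_ROLE_COLUMNS))


@dataclass
class RawTrial:
    """One trial's time-stamped multichannel kinematic matrix.

    ``time_ms`` is strictly increasing with uniform spacing; a standard
    trial has 48,000 rows, 5 ms spacing (200 Hz) and 320 channels.
    """

    time_ms: np.ndarray
    channels: np.ndarray
    channel_names: list[str]
    key: TrialKey | None = None

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.channels = np.asarray(self.channels, dtype=float)
        self.validate()
        self._index = {name: i for i, name in enumerate(self.channel_names)}

    def validate(self) -> None:
        if self.time_ms.ndim != 1 or self.time_ms.size < 2:
            raise SchemaError("trial must have at least two timestamps")
        if self.channels.shape != (self.time_ms.size, len(self.channel_names)):
            raise SchemaError(
                f"channel matrix shape {self.channels.shape} does not match "
                f"{self.time_ms.size} timestamps x {len(self.channel_names)} names"
            )
        dt = np.diff(self.time_ms)
        if np.any(dt <= 0):
            raise SchemaError("timestamps must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise SchemaError("timestamps must be uniformly spaced")
        if not (np.all(np.isfinite(self.time_ms)) and np.all(np.isfinite(self.channels))):
            raise SchemaError("trial contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.time_ms.size

    @property
    def fs(self) -> float:
        """Sampling rate in Hz, inferred from the timestamp spacing."""
        return 1000.0 / float(self.time_ms[1] - self.time_ms[0])

    @property
    def duration_s(self) -> float:
        return float(self.time_ms[-1] - self.time_ms[0]) / 1000.0 + 1.0 / self.fs

    @property
    def time_s(self) -> np.ndarray:
        """Sample times in seconds from trial start."""
        return (self.time_ms - self.time_ms[0]) / 1000.0

    def get(self, column: str) -> np.ndarray:
        if column not in self._index:
            raise SchemaError(f"no channel named {column!r}")
        return self.channels[:, self._index[column]]

    def role(self, channel_map: ChannelMap, role: str) -> np.ndarray:
        return self.get(channel_map.column(role))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.channels, columns=list(self.channel_names))
        df.insert(0, "Time", self.time_ms)
        return df


def write_raw_trial(trial: RawTrial, path: str | Path, float_format: str = "%.6g") -> Path:
    """Write a trial as CSV with a ``Time`` (ms) first column.

    Fixed 6-significant-digit formatting keeps written fixtures bit-stable.
    """
    if trial.n_samples == 0:
        raise SchemaError("refusing to write an empty trial")
    path = Path(path)
    trial.to_dataframe().to_csv(path, index=False, float_format=float_format)
    return path


def read_raw_trial(
    path: str | Path,
    channel_map: ChannelMap | None = None,
    required_roles: Iterable[str] | None = None,
    key: TrialKey | None = None,
) -> RawTrial:
    """Read a raw-trial CSV and validate its invariants.

    The first column must hold timestamps in milliseconds; uniform spacing is
    enforced. If ``channel_map`` is given, the mapped (or ``required_roles``)
    columns must be present.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: expected a Time column plus channels")
    if df.isna().any().any():
        raise SchemaError(f"{path}: missing values in raw trial")
    if key is None:
        try:
            key = parse_trial_id(Path(path).stem)
        except TrialIdError:
            key = None
    trial = RawTrial(
        time_ms=df.iloc[:, 0].to_numpy(dtype=float),
        channels=df.iloc[:, 1:].to_numpy(dtype=float),
        channel_names=[str(c) for c in df.columns[1:]],
        key=key,
    )
    if channel_map is not None:
        channel_map.validate(trial, required_roles)
    return trial


@dataclass
class GaitParameterTable:
    """The 26 published spatiotemporal series for one trial.

    Rows are aligned by sample index; series of different natural length are
    padded with NaN (written as empty cells). Column order is fixed.
    """

    data: pd.DataFrame
    key: TrialKey | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        cols = tuple(self.data.columns)
        if cols != GAIT_TABLE_COLUMNS:
            raise SchemaError(
                f"gait table must have the 26 canonical columns in order; got "
                f"{len(cols)} columns"
            )
        values = self.data.to_numpy(dtype=float)
        finite = values[np.isfinite(values)]
        if finite.size and finite.min() <= 0:
            raise SchemaError("gait parameters must all be positive")
        for side in ("left", "right"):
            total = (
                self.data[f"{side} pct stance (%GC)"]
                + self.data[f"{side} pct swing (%GC)"]
            ).dropna()
            if not np.allclose(total, 100.0, atol=1e-9):
                raise SchemaError(f"{side} pct stance + pct swing must equal 100")

    def column(self, name: str) -> np.ndarray:
        """A series without its NaN padding."""
        return self.data[name].dropna().to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


def write_gait_table(table: GaitParameterTable, path: str | Path,
                     float_format: str = "%.6g") -> Path:
    path = Path(path)
    table.data.to_csv(path, index=False, float_format=float_format, na_rep="")
    return path


def read_gait_table(path: str | Path, key: TrialKey | None = None) -> GaitParameterTable:
    df = pd.read_csv(path)
    if tuple(df.columns) != GAIT_TABLE_COLUMNS:
        raise SchemaError(
            f"{path}: expected the 26 canonical gait-table columns, got "
            f"{df.shape[1]}"
        )
    if key is None:
        try:
            key = parse_trial_id(Path(path).stem)
        except TrialIdError:
            key = None
    return GaitParameterTable(data=df.astype(float), key=key)
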