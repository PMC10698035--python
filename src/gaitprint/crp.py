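"""Continuous relative phase (CRP) between bilateral segment pitch angles.

Each gait cycle (heel strike to next heel strike of the reference foot) is
time-normalized to 100 points and centered,

    x_centered(t_i) = x(t_i) - min(x) - (max(x) - min(x)) / 2,

so the segment phase angle orbits 0 deg. The analytic signal is obtained
via the Hilbert transform, zeta(t) = x_centered(t) + i H(t), and the
segment phase angle is the four-quadrant angle phi(t) =
atan2(H(t), x_centered(t)). The relative phase is

    Phi(t_i) = phi_right(t_i) - phi_left(t_i),

wrapped to [0, 360): 0 deg means the segments move in-phase, 180 deg
anti-phase — the expected bilateral relation in healthy walking. The trial
summary Phi-bar is the circular mean over all normalized points of all
cycles (an arithmetic mean would be wrap-biased near 180 deg).

Finite-window Hilbert bias at the cycle edges is mitigated by mirror-
padding 10 points on each side before the transform and discarding them
after.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .errors import AnalysisError

__all__ = [
    "PhaseSeries",
    "CrpResult",
    "center_series",
    "normalize_cycle",
    "segment_phase",
    "crp_series",
    "crp_from_events",
]

#: Points per normalized gait cycle.
N_CYCLE_POINTS = 100

#: Mirror padding (points per side) applied before the Hilbert transform.
_HILBERT_PAD = 10


@dataclass
class PhaseSeries:
    """A segment angle series with its analytic-signal decomposition."""

    x: np.ndarray            # original angles, deg
    x_centered: np.ndarray   # centered angles, deg
    hilbert_part: np.ndarray  # imaginary part H(t) of the analytic signal
    phi: np.ndarray          # segment phase angle, deg, in (-180, 180]


@dataclass
class CrpResult:
    """Per-cycle relative-phase curves and their trial-level summary."""

    cycles: np.ndarray       # (n_cycles, 100) Phi curves, deg, in [0, 360)
    mean_phi: float          # circular mean of all points, deg, in [0, 360)
    circular_sd: float       # circular SD, deg
    n_cycles: int
    anomalous: bool          # |mean - 180| beyond the anomaly threshold

    def __post_init__(self) -> None:
        if self.cycles.ndim != 2 or self.cycles.shape[1] != N_CYCLE_POINTS:
            raise AnalysisError("cycle curves must have exactly 100 points")
        if not 0.0 <= self.mean_phi < 360.0:
            raise AnalysisError("mean Phi must lie in [0, 360)")


def center_series(x) -> np.ndarray:
    """Center an angle series so its extrema are symmetric about zero.

    Applies x - min(x) - (max(x) - min(x))/2. A constant series has zero
    range; it is returned as all zeros with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise AnalysisError("need at least 2 samples to center")
    rng = x.max() - x.min()
    if rng == 0.0:
        warnings.warn("constant series: centered to all zeros", stacklevel=2)
        return np.zeros_like(x)
    return x - x.min() - rng / 2.0


def normalize_cycle(segment, n: int = N_CYCLE_POINTS) -> np.ndarray:
    """Resample one cycle to ``n`` evenly spaced points, endpoints preserved."""
    segment = np.asarray(segment, dtype=float)
    if segment.size < 2:
        raise AnalysisError("cycle must contain at least 2 samples")
    if n < 2:
        raise AnalysisError("normalized length must be >= 2")
    old = np.linspace(0.0, 1.0, segment.size)
    new = np.linspace(0.0, 1.0, n)
    if segment.size < 4:
        return np.interp(new, old, segment)
    # Cubic interpolation: linear segments reproduced exactly, smooth cycles
    # resampled with negligible distortion.
    from scipy.interpolate import CubicSpline

    return CubicSpline(old, segment)(new)


def _analytic_phase(x_centered: np.ndarray,
                    pad: int = _HILBERT_PAD) -> tuple[np.ndarray, np.ndarray]:
    """Hilbert imaginary part and four-quadrant phase.

    ``pad`` mirror points per side mitigate the finite-window transform bias
    of short cycle segments; for long (near-periodic) series no padding is
    needed and ``pad=0`` keeps the transform exact.
    """
    pad = min(pad, x_centered.size - 1)
    if pad:
        padded = np.concatenate([
            x_centered[pad:0:-1], x_centered, x_centered[-2:-2 - pad:-1]
        ])
        h = np.imag(hilbert(padded))[pad:-pad]
    else:
        h = np.imag(hilbert(x_centered))
    phi = np.degrees(np.arctan2(h, x_centered))
    return h, phi


def segment_phase(x) -> PhaseSeries:
    """Segment phase angle of an angle series via the analytic signal.

    The input is centered first; the phase is the four-quadrant angle of
    (x_centered, H(t)), in degrees in (-180, 180].
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise AnalysisError("need at least 8 samples for a phase estimate")
    if x.max() == x.min():
        raise AnalysisError("constant series has no phase")
    xc = center_series(x)
    h, phi = _analytic_phase(xc, pad=0)
    return PhaseSeries(x=x, x_centered=xc, hilbert_part=h, phi=phi)


def _circular_summary(phi_deg: np.ndarray) -> tuple[float, float]:
    rad = np.deg2rad(phi_deg)
    z = np.exp(1j * rad).mean()
    mean = float(np.degrees(np.angle(z)) % 360.0)
    r = min(1.0, abs(z))
    sd = float(np.degrees(np.sqrt(-2.0 * np.log(max(r, 1e-300)))))
    return mean, sd


def crp_series(
    right,
    left,
    cycle_bounds: np.ndarray,
    fs: float = 1.0,
    anomaly_threshold: float = 20.0,
) -> CrpResult:
    """Continuous relative phase between two segment angle series.

    Parameters
    ----------
    right, left : array-like
        Equal-length angle series (deg) at the same sampling rate.
    cycle_bounds : array-like
        Heel-strike times (s) of the reference foot delimiting gait cycles;
        cycle k spans [bounds[k], bounds[k+1]). At least one complete cycle
        is required.
    fs : float
        Sampling rate (Hz) used to convert bounds to sample indices.
    anomaly_threshold : float
        A trial is flagged anomalous when |mean Phi - 180| exceeds this
        (deg); deviations from anti-phase are diagnostic of bad data.
    """
    right = np.asarray(right, dtype=float)
    left = np.asarray(left, dtype=float)
    if right.shape != left.shape or right.ndim != 1:
        raise AnalysisError("right and left series must be equal-length 1-D")
    bounds = np.asarray(cycle_bounds, dtype=float)
    idx = np.round(bounds * fs).astype(int)
    idx = idx[(idx >= 0) & (idx <= right.size)]
    if idx.size < 2:
        raise AnalysisError("no complete gait cycles in the series")

    curves = []
    for a, b in zip(idx[:-1], idx[1:]):
        if b - a < 4:
            continue
        phis = {}
        for name, sig in (("r", right), ("l", left)):
            cyc = normalize_cycle(sig[a:b + 1 if b < sig.size else b])
            xc = center_series(cyc)
            if np.all(xc == 0.0):
                raise AnalysisError("constant cycle segment")
            _, phi = _analytic_phase(xc)
            phis[name] = phi
        curves.append(np.mod(phis["r"] - phis["l"], 360.0))
    if not curves:
        raise AnalysisError("no usable gait cycles")
    cycles = np.vstack(curves)
    mean, sd = _circular_summary(cycles.ravel())
    return CrpResult(
        cycles=cycles,
        mean_phi=mean,
        circular_sd=sd,
        n_cycles=cycles.shape[0],
        anomalous=abs(mean - 180.0) > anomaly_threshold,
    )


def crp_from_events(trial, channel_map, events, segment: str = "thigh",
                    anomaly_threshold: float = 20.0) -> CrpResult:
    """CRP of a bilateral segment pair cut at right-foot heel strikes."""
    right = trial.role(channel_map, f"{segment}_pitch_r")
    left = trial.role(channel_map, f"{segment}_pitch_l")
    return crp_series(right, left, events.hs_r, fs=trial.fs,
                      anomaly_threshold=anomaly_threshold)
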