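"""Synthetic walking trials and fractional Gaussian noise with known truth.

The generator emulates the structure of an IMU overground-walking export:
four-minute trials at 200 Hz, left/right thigh/shank/foot pitch-angle
channels in anti-phase, foot and pelvis position channels, and
stride-interval series with tunable long-range correlation (Hurst exponent
H). Stride-to-stride fluctuations of stride time and stride length are
driven by exact fractional Gaussian noise (fGn), synthesized by circulant
(Davies-Harte) embedding of the closed-form fGn autocovariance

    rho(k) = 1/2 (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}),

so that recovery tests against the injected H are meaningful.

The kinematic waveforms are smooth periodic cycle templates warped onto the
stride timeline; only the phase relations and the event geometry (heel
strike, toe off, foot placement) are meant to be faithful, not full 3-D
body dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np

from .core_io import RawTrial, TrialKey, standard_channel_names, _ROLE_COLUMNS
from .errors import AnalysisError, GenerationError

__all__ = [
    "FgnSpec",
    "TrialConfig",
    "SyntheticTruth",
    "fgn_autocorrelation",
    "simulate_fgn",
    "simulate_trial",
]


@dataclass(frozen=True)
class FgnSpec:
    """Parameters of a fractional Gaussian noise series."""

    h: float
    n: int
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.h <= 1.0:
            raise AnalysisError(f"Hurst exponent must lie in (0, 1], got {self.h}")
        if self.n < 2:
            raise AnalysisError(f"series length must be >= 2, got {self.n}")
        if not self.sigma > 0:
            raise AnalysisError(f"sigma must be positive, got {self.sigma}")


def fgn_autocorrelation(h: float, k) -> np.ndarray | float:
    """Closed-form fGn autocorrelation rho(k) at integer lag(s) ``k >= 0``.

    rho(0) = 1; for H = 0.5 all positive lags vanish (white noise); for
    H > 0.5 the tail decays as a power law (persistent, "pink-noise-like").
    """
    if not 0.0 < h <= 1.0:
        raise AnalysisError(f"Hurst exponent must lie in (0, 1], got {h}")
    k_arr = np.asarray(k, dtype=float)
    if np.any(k_arr < 0):
        raise AnalysisError("lag must be >= 0")
    two_h = 2.0 * h
    rho = 0.5 * (
        np.abs(k_arr + 1) ** two_h
        - 2.0 * np.abs(k_arr) ** two_h
        + np.abs(k_arr - 1) ** two_h
    )
    if np.isscalar(k) or k_arr.ndim == 0:
        return float(rho)
    return rho


def simulate_fgn(spec: FgnSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Exact stationary fGn by circulant embedding of the autocovariance.

    The circulant extension of the fGn autocovariance has nonnegative
    eigenvalues for H in (0, 1], so the construction is exact: the returned
    series is Gaussian with autocovariance sigma^2 * rho(k). Deterministic
    given ``spec.seed`` (ignored if an explicit ``rng`` is passed).
    """
    n = spec.n
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.h == 1.0:
        # Degenerate perfectly-correlated case: one shared Gaussian draw.
        return np.full(n, spec.sigma * rng.standard_normal())
    r = fgn_autocorrelation(spec.h, np.arange(n + 1))
    # Circulant first row: r_0 ... r_n, r_{n-1} ... r_1 (length 2n).
    c = np.concatenate([r, r[-2:0:-1]])
    lam = np.fft.rfft(c).real
    if lam.min() < -1e-8 * lam.max():
        raise GenerationError(
            f"circulant embedding produced negative eigenvalues for H={spec.h}"
        )
    lam = np.clip(lam, 0.0, None)
    m = 2 * n
    # Hermitian-symmetric complex Gaussian spectrum -> real series via irfft.
    half = lam.size  # n + 1 frequencies for rfft of length-2n input
    u = rng.standard_normal(half)
    v = rng.standard_normal(half)
    w = np.empty(half, dtype=complex)
    w[0] = np.sqrt(lam[0] * m) * u[0]
    w[-1] = np.sqrt(lam[-1] * m) * u[-1]
    w[1:-1] = np.sqrt(lam[1:-1] * m / 2.0) * (u[1:-1] + 1j * v[1:-1])
    x = np.fft.irfft(w, n=m)[:n]
    return spec.sigma * x


# ---------------------------------------------------------------------------
# Full-trial generator
# ---------------------------------------------------------------------------

#: Fraction of the gait cycle spent in stance (typical adult duty factor).
DEFAULT_DUTY_FACTOR = 0.62


@dataclass(frozen=True)
class TrialConfig:
    """Generator configuration for one synthetic walking trial.

    Defaults describe a standard four-minute self-paced trial: 240 s at
    200 Hz (48,000 samples), mean stride time 1.1 s, mean stride length
    1.35 m, step width 0.12 m, perfect left-right anti-phase, persistent
    stride-interval fluctuations.
    """

    duration_s: float = 240.0
    fs: float = 200.0
    mean_stride_time: float = 1.1        # s
    stride_time_sd: float = 0.02         # s
    stride_time_h: float = 0.75          # Hurst exponent of stride fluctuations
    mean_stride_length: float = 1.35     # m
    stride_length_sd: float = 0.025      # m
    length_time_coupling: float = 0.5    # corr(stride length, stride time) driver
    step_width: float = 0.12             # m, lateral heel-to-line distance
    phase_offset: float = 0.5            # left-right offset, fraction of cycle
    duty_factor: float = DEFAULT_DUTY_FACTOR
    swing_height: float = 0.05           # m, peak foot lift during swing
    pelvis_height: float = 0.95          # m
    noise_std_angle: float = 0.0         # deg, additive measurement noise
    noise_std_pos: float = 0.0           # m, additive measurement noise
    drift_rate: float = 0.0              # m/s horizontal-plane drift magnitude
    drift_azimuth_deg: float = 90.0      # drift direction, 0 = progression axis
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise GenerationError(
                f"duration*fs must be an integer sample count, got {n}"
            )
        if self.mean_stride_time < 0.4:
            raise GenerationError("mean stride time must be >= 0.4 s")
        if not 0.0 < self.duty_factor < 1.0:
            raise GenerationError("duty factor must lie in (0, 1)")
        if not 0.0 <= self.phase_offset < 1.0:
            raise GenerationError("phase offset must lie in [0, 1)")
        if not 0.0 < self.stride_time_h <= 1.0:
            raise GenerationError("stride-time H must lie in (0, 1]")
        if not -1.0 <= self.length_time_coupling <= 1.0:
            raise GenerationError("length-time coupling must lie in [-1, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class SyntheticTruth:
    """Ground truth of a generated trial, for parameter-recovery tests.

    Event times are seconds from trial start; only events inside the trial
    window are kept. ``stride_times_*`` are successive same-foot heel-strike
    differences; ``stride_lengths_*`` are the matching landing-to-landing
    progressions, in meters.
    """

    hs_r: np.ndarray
    to_r: np.ndarray
    hs_l: np.ndarray
    to_l: np.ndarray
    stride_times_r: np.ndarray
    stride_times_l: np.ndarray
    stride_lengths_r: np.ndarray
    stride_lengths_l: np.ndarray
    landing_x_r: np.ndarray
    landing_x_l: np.ndarray
    step_width: float
    stride_time_h: float
    phase_offset: float
    mean_speed: float
    drift_rate: float

    def __post_init__(self) -> None:
        for name in ("hs_r", "hs_l", "to_r", "to_l"):
            t = getattr(self, name)
            if t.size > 1 and np.any(np.diff(t) <= 0):
                raise GenerationError(f"truth events {name} not strictly increasing")


def _cycle_template(u: np.ndarray, amp: float, phase: float, harm2: float) -> np.ndarray:
    """Smooth one-cycle waveform: dominant first harmonic plus a small second."""
    return amp * np.cos(2 * np.pi * u - phase) + harm2 * np.sin(4 * np.pi * u)


def _swing_profile(w: np.ndarray) -> np.ndarray:
    """Monotone 0->1 progression profile with zero end slopes."""
    return w - np.sin(2 * np.pi * w) / (2 * np.pi)


def simulate_trial(config: TrialConfig | None = None,
                   key: TrialKey | None = None) -> tuple[RawTrial, SyntheticTruth]:
    """Generate one synthetic walking trial plus its ground truth.

    Stride intervals are drawn as mean + fGn fluctuations; a continuous gait
    phase (one unit per right stride) warps one-cycle templates onto the
    stride timeline. The left side is offset by ``phase_offset`` cycles
    (0.5 = perfect anti-phase). Foot positions advance by per-stride lengths
    with alternating lateral offsets giving the target step width; the
    pelvis advances at the instantaneous stride speed. Optional additive
    measurement noise and horizontal-plane drift.
    """
    cfg = config if config is not None else TrialConfig()
    n = cfg.n_samples
    dt = 1.0 / cfg.fs
    t = np.arange(n) * dt

    master = np.random.SeedSequence(cfg.seed)
    ss_time, ss_len, ss_noise = master.spawn(3)
    rng_time = np.random.default_rng(ss_time)
    rng_len = np.random.default_rng(ss_len)
    rng_noise = np.random.default_rng(ss_noise)

    # Stride-interval series (right-foot strides), margin for edges.
    n_strides = int(np.ceil(cfg.duration_s / cfg.mean_stride_time)) + 6
    z_time = simulate_fgn(FgnSpec(cfg.stride_time_h, n_strides), rng=rng_time)
    z_len_ind = simulate_fgn(FgnSpec(cfg.stride_time_h, n_strides), rng=rng_len)
    c = cfg.length_time_coupling
    z_len = c * z_time + np.sqrt(max(0.0, 1.0 - c * c)) * z_len_ind

    stride_times = cfg.mean_stride_time + cfg.stride_time_sd * z_time
    stride_lengths = cfg.mean_stride_length + cfg.stride_length_sd * z_len
    if np.any(stride_times <= 0):
        raise GenerationError("drawn stride times include non-positive values")
    if np.any(stride_lengths <= 0):
        raise GenerationError("drawn stride lengths include non-positive values")

    # Right heel-strike knots: theta(hs_k) = k (theta = gait phase, cycles).
    t0 = 0.3  # first right heel strike, s
    hs_knots = t0 + np.concatenate([[0.0], np.cumsum(stride_times)])
    theta_knots = np.arange(hs_knots.size, dtype=float)
    # Extend for extrapolation before the first / after the last knot.
    t_ext = np.concatenate([[hs_knots[0] - 2 * stride_times[0]], hs_knots,
                            [hs_knots[-1] + 2 * stride_times[-1]]])
    th_ext = np.concatenate([[-2.0], theta_knots, [theta_knots[-1] + 2.0]])
    theta = np.interp(t, t_ext, th_ext)

    # Pelvis progression P(theta): piecewise linear, one stride length/cycle.
    p_knots = np.concatenate([[0.0], np.cumsum(stride_lengths)])
    p_ext = np.concatenate([[-2 * stride_lengths[0]], p_knots,
                            [p_knots[-1] + 2 * stride_lengths[-1]]])

    def progression(th: np.ndarray) -> np.ndarray:
        return np.interp(th, th_ext, p_ext)

    duty = cfg.duty_factor

    def foot_xz(th_foot: np.ndarray, landing_phase: float) -> tuple[np.ndarray, np.ndarray]:
        """Forward position and vertical lift of a foot from its stride phase."""
        kf = np.floor(th_foot)
        u = th_foot - kf
        x_now = progression(kf + landing_phase)
        x_next = progression(kf + 1.0 + landing_phase)
        w = np.clip((u - duty) / (1.0 - duty), 0.0, 1.0)
        x = x_now + (x_next - x_now) * _swing_profile(w)
        in_swing = u >= duty
        z = np.where(
            in_swing,
            cfg.swing_height * np.sin(np.pi * np.clip((u - duty) / (1.0 - duty), 0, 1)) ** 2,
            0.0,
        )
        return x, z

    po = cfg.phase_offset
    u_r = np.mod(theta, 1.0)
    u_l = np.mod(theta - po, 1.0)

    x_foot_r, z_foot_r = foot_xz(theta, 0.0)
    x_foot_l, z_foot_l = foot_xz(theta - po, po)
    y_foot_r = np.full(n, -cfg.step_width / 2.0)
    y_foot_l = np.full(n, +cfg.step_width / 2.0)

    pelvis_x = progression(theta)
    pelvis_y = np.zeros(n)
    pelvis_z = np.full(n, cfg.pelvis_height)

    channels = {}
    for side, u in (("r", u_r), ("l", u_l)):
        channels[f"thigh_pitch_{side}"] = _cycle_template(u, 20.0, 0.0, 2.0)
        channels[f"shank_pitch_{side}"] = _cycle_template(u, 28.0, 0.6, 3.0)
        channels[f"foot_pitch_{side}"] = _cycle_template(u, 16.0, 1.1, 1.5)
    channels["foot_pos_x_r"], channels["foot_pos_z_r"] = x_foot_r, z_foot_r
    channels["foot_pos_x_l"], channels["foot_pos_z_l"] = x_foot_l, z_foot_l
    channels["foot_pos_y_r"], channels["foot_pos_y_l"] = y_foot_r, y_foot_l
    channels["pelvis_pos_x"] = pelvis_x
    channels["pelvis_pos_y"] = pelvis_y
    channels["pelvis_pos_z"] = pelvis_z
    channels["foot_gyro_pitch_r"] = np.gradient(channels["foot_pitch_r"], dt)
    channels["foot_gyro_pitch_l"] = np.gradient(channels["foot_pitch_l"], dt)

    # Measurement noise (angles in deg, positions in m).
    if cfg.noise_std_angle > 0:
        for name in list(channels):
            if "pitch" in name and "gyro" not in name:
                channels[name] = channels[name] + cfg.noise_std_angle * \
                    rng_noise.standard_normal(n)
    if cfg.noise_std_pos > 0:
        for name in list(channels):
            if "pos" in name:
                channels[name] = channels[name] + cfg.noise_std_pos * \
                    rng_noise.standard_normal(n)

    # Horizontal-plane drift: displaces all horizontal positions by
    # drift_rate * t along the drift azimuth; vertical channels untouched.
    if cfg.drift_rate != 0.0:
        az = np.deg2rad(cfg.drift_azimuth_deg)
        dx = cfg.drift_rate * t * np.cos(az)
        dy = cfg.drift_rate * t * np.sin(az)
        for name in list(channels):
            if "pos_x" in name:
                channels[name] = channels[name] + dx
            elif "pos_y" in name:
                channels[name] = channels[name] + dy

    names = standard_channel_names()
    matrix = np.zeros((n, len(names)))
    col_of = {name: i for i, name in enumerate(names)}
    for role, series in channels.items():
        matrix[:, col_of[_ROLE_COLUMNS[role]]] = series

    trial = RawTrial(time_ms=t * 1000.0, channels=matrix,
                     channel_names=names, key=key)

    truth = _build_truth(cfg, hs_knots, theta_knots, th_ext, t_ext, p_ext)
    return trial, truth


def _event_times(theta_values: np.ndarray, th_ext: np.ndarray,
                 t_ext: np.ndarray) -> np.ndarray:
    """Invert the (piecewise-linear, increasing) gait phase at given phases."""
    return np.interp(theta_values, th_ext, t_ext)


def _build_truth(cfg: TrialConfig, hs_knots: np.ndarray, theta_knots: np.ndarray,
                 th_ext: np.ndarray, t_ext: np.ndarray,
                 p_ext: np.ndarray) -> SyntheticTruth:
    duration = cfg.duration_s
    po, duty = cfg.phase_offset, cfg.duty_factor

    def progression(th: np.ndarray) -> np.ndarray:
        return np.interp(th, th_ext, p_ext)

    def clip_window(times: np.ndarray, phases: np.ndarray):
        keep = (times >= 0.0) & (times < duration)
        return times[keep], phases[keep]

    hs_r, ph_r = clip_window(hs_knots, theta_knots)
    to_r_all = _event_times(theta_knots + duty, th_ext, t_ext)
    to_r, _ = clip_window(to_r_all, theta_knots + duty)

    ph_l_all = theta_knots + po
    hs_l_all = _event_times(ph_l_all, th_ext, t_ext)
    hs_l, ph_l = clip_window(hs_l_all, ph_l_all)
    to_l_all = _event_times(ph_l_all + duty, th_ext, t_ext)
    to_l, _ = clip_window(to_l_all, ph_l_all + duty)

    landing_x_r = progression(ph_r)
    landing_x_l = progression(ph_l)
    mean_speed = float(
        (progression(np.interp(duration, t_ext, th_ext))
         - progression(np.interp(0.0, t_ext, th_ext))) / duration
    )

    return SyntheticTruth(
        hs_r=hs_r, to_r=to_r, hs_l=hs_l, to_l=to_l,
        stride_times_r=np.diff(hs_r),
        stride_times_l=np.diff(hs_l),
        stride_lengths_r=np.diff(landing_x_r),
        stride_lengths_l=np.diff(landing_x_l),
        landing_x_r=landing_x_r, landing_x_l=landing_x_l,
        step_width=cfg.step_width,
        stride_time_h=cfg.stride_time_h,
        phase_offset=po,
        mean_speed=mean_speed,
        drift_rate=cfg.drift_rate,
    )
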