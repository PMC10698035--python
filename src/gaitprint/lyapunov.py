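"""State-space reconstruction and Wolf's largest Lyapunov exponent.

A scalar series is embedded into delay vectors
``[x(t), x(t+tau), ..., x(t+(m-1)tau)]``. The delay tau is chosen at the
first local minimum of the average mutual information (AMI, equiprobable
binning; fallback: first drop below AMI(0)/e), the dimension m as the
smallest with a false-nearest-neighbor fraction below threshold.

Wolf's algorithm tracks a reference trajectory and its nearest neighbor
(outside a Theiler window), evolves both a fixed number of steps, and
accumulates log(d'/d), the log ratio of the separations after and before
evolution; when the separation grows beyond a fraction of the attractor
extent the neighbor is replaced by a point that is close again and keeps
the orientation of the separation vector (bounded replacement angle). The
exponent is the accumulated log divergence normalized by the total evolved
time:

    lambda_1 = (1 / total time) * sum log(d'_k / d_k),

in nats/s by default (bits/s optional). A smaller lambda_1 means less
divergence — more predictable cycles. The estimate is exactly invariant to
translating or uniformly scaling the trajectory since only distance ratios
enter, with search radii defined relative to the attractor extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import AnalysisError

__all__ = [
    "EmbeddingSpec",
    "AmiResult",
    "FnnResult",
    "LleResult",
    "average_mutual_information",
    "false_nearest_neighbors",
    "delay_embed",
    "wolf_lle",
    "lyapunov_exponent",
]

#: Minimum trajectory length Wolf's algorithm will accept.
_MIN_TRAJECTORY = 500


@dataclass(frozen=True)
class EmbeddingSpec:
    """Delay-embedding parameters: delay tau (samples) and dimension."""

    tau: int
    dim: int

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise AnalysisError(f"tau must be >= 1, got {self.tau}")
        if self.dim < 1:
            raise AnalysisError(f"dim must be >= 1, got {self.dim}")

    def n_vectors(self, n: int) -> int:
        return n - (self.dim - 1) * self.tau


@dataclass
class AmiResult:
    """AMI curve (bits) per lag and the selected delay."""

    lags: np.ndarray
    ami: np.ndarray
    tau: int
    used_fallback: bool


@dataclass
class FnnResult:
    """False-neighbor fraction per dimension and the selected dimension."""

    dims: np.ndarray
    fractions: np.ndarray
    dim: int


@dataclass
class LleResult:
    """Largest Lyapunov exponent with evolution diagnostics."""

    lambda1: float
    units: str               # "nats/s" or "bits/s"
    spec: EmbeddingSpec | None
    d_initial: np.ndarray    # separation before each evolution segment
    d_final: np.ndarray      # separation after each evolution segment
    evolution_times: np.ndarray  # seconds per segment
    n_replacements: int

    def __post_init__(self) -> None:
        if np.any(self.d_initial <= 0) or np.any(self.d_final <= 0):
            raise AnalysisError("neighbor separations must be positive")
        if np.any(self.evolution_times <= 0):
            raise AnalysisError("evolution times must be positive")


def _equiprobable_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Rank-based digitization into ``bins`` (near-)equal-occupancy bins."""
    ranks = np.argsort(np.argsort(x, kind="stable"), kind="stable")
    return (ranks * bins) // x.size


def average_mutual_information(x, max_lag: int = 100, bins: int = 16,
                               smooth: int = 5) -> AmiResult:
    """AMI (bits) of a series against its lagged copies; selects the delay.

    The delay is the first local minimum of the AMI curve. Because histogram
    AMI is locally jagged, the curve is first smoothed with a short moving
    average (width ``smooth``) and a minimum must be the lowest value within
    its +-``smooth``-lag window. When no such minimum exists within
    ``max_lag`` the first lag where AMI drops below AMI(0)/e is used
    (fallback), then ``max_lag`` itself.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 10 * max_lag:
        raise AnalysisError(
            f"series of {x.size} too short for max_lag={max_lag} (need 10x)"
        )
    if np.ptp(x) == 0.0:
        raise AnalysisError("constant series has no mutual information")
    symbols = _equiprobable_bins(x, bins)
    lags = np.arange(max_lag + 1)
    ami = np.empty(lags.size)
    for i, lag in enumerate(lags):
        a = symbols[: x.size - lag]
        b = symbols[lag:]
        joint = np.zeros((bins, bins))
        np.add.at(joint, (a, b), 1.0)
        joint /= a.size
        pa = joint.sum(axis=1, keepdims=True)
        pb = joint.sum(axis=0, keepdims=True)
        mask = joint > 0
        ami[i] = np.sum(joint[mask] * np.log2(joint[mask] / (pa @ pb)[mask]))
    tau, fallback = None, False
    w = max(1, smooth)
    pad = w // 2
    padded = np.concatenate([ami[pad:0:-1], ami, ami[-2:-2 - pad:-1]])
    sm = np.convolve(padded, np.ones(w) / w, mode="valid")
    for k in range(1, sm.size - 1):
        lo, hi = max(0, k - w), min(sm.size, k + w + 1)
        if sm[k] == sm[lo:hi].min() and sm[k] < sm[k - 1]:
            tau = k
            break
    if tau is None:
        fallback = True
        below = np.flatnonzero(ami[1:] < ami[0] / np.e)
        tau = int(below[0] + 1) if below.size else max_lag
    return AmiResult(lags=lags, ami=ami, tau=int(tau), used_fallback=fallback)


def delay_embed(x, spec: EmbeddingSpec) -> np.ndarray:
    """Trajectory matrix of delay vectors; rows = n - (dim-1)*tau."""
    x = np.asarray(x, dtype=float).ravel()
    rows = spec.n_vectors(x.size)
    if rows < 2:
        raise AnalysisError(
            f"series of {x.size} too short for dim={spec.dim}, tau={spec.tau}"
        )
    return np.column_stack(
        [x[j * spec.tau: j * spec.tau + rows] for j in range(spec.dim)]
    )


def false_nearest_neighbors(
    x,
    tau: int,
    max_dim: int = 10,
    rtol: float = 15.0,
    atol: float = 2.0,
    threshold: float = 0.01,
    theiler: int | None = None,
) -> FnnResult:
    """False-nearest-neighbor fractions; selects the embedding dimension.

    For each dimension d the nearest neighbor of every delay vector is
    found (excluding a Theiler window of ``tau`` by default); the neighbor
    is false when adding the (d+1)-th coordinate stretches the distance by
    more than ``rtol``, or moves the pair apart by more than ``atol`` times
    the series SD. The selected dimension is the smallest whose false
    fraction falls below ``threshold``.
    """
    x = np.asarray(x, dtype=float).ravel()
    sd = x.std()
    if sd == 0.0:
        raise AnalysisError("constant series")
    if theiler is None:
        theiler = tau
    dims = np.arange(1, max_dim + 1)
    fractions = np.full(dims.size, np.nan)
    selected = None
    for di, d in enumerate(dims):
        spec_d = EmbeddingSpec(tau=tau, dim=int(d))
        rows_next = x.size - d * tau  # vectors that still have a (d+1)-th coord
        if rows_next < 10:
            raise AnalysisError(
                f"series of {x.size} too short for max_dim={max_dim} at tau={tau}"
            )
        traj = delay_embed(x, spec_d)[:rows_next]
        tree = cKDTree(traj)
        k = min(2 * theiler + 5, rows_next)
        dist, idx = tree.query(traj, k=k)
        false = 0
        counted = 0
        degenerate = 1e-8 * sd
        for i in range(rows_next):
            j = -1
            for cand, dc in zip(idx[i], dist[i]):
                if abs(cand - i) > theiler:
                    j = cand
                    dij = dc
                    break
            if j < 0:
                continue
            counted += 1
            extra = abs(x[i + d * tau] - x[j + d * tau])
            # Numerically coincident points (exact repeats of a noise-free
            # orbit) are true neighbors by construction.
            if dij <= degenerate:
                if extra > degenerate:
                    false += 1
                continue
            new_dist = np.hypot(dij, extra)
            if extra / dij > rtol or new_dist / sd > atol:
                false += 1
        fractions[di] = false / counted if counted else np.nan
        if selected is None and counted and fractions[di] < threshold:
            selected = int(d)
    if selected is None:
        selected = int(dims[np.nanargmin(fractions)])
    return FnnResult(dims=dims, fractions=fractions, dim=selected)


def _dominant_period(x: np.ndarray) -> int:
    """Mean period in samples from the dominant FFT frequency."""
    xc = x - x.mean()
    spec = np.abs(np.fft.rfft(xc))
    spec[0] = 0.0
    k = int(np.argmax(spec))
    return max(1, int(round(x.size / k))) if k else x.size


def wolf_lle(
    trajectory: np.ndarray,
    fs: float,
    evolve: int = 3,
    min_scale_frac: float = 1e-4,
    max_scale_frac: float = 0.1,
    max_angle_deg: float = 30.0,
    theiler: int | None = None,
    base: str = "nats",
    spec: EmbeddingSpec | None = None,
) -> LleResult:
    """Largest Lyapunov exponent of a reconstructed trajectory (Wolf).

    Parameters
    ----------
    trajectory : (n, dim) array
        Delay-embedded trajectory, n >= 500.
    fs : float
        Sampling rate of the underlying series (Hz); the exponent is
        reported per second.
    evolve : int
        Samples each reference/neighbor pair is evolved between distance
        measurements.
    min_scale_frac, max_scale_frac : float
        Neighbor-search distance bounds as fractions of the attractor
        extent (RMS radius about the centroid); a pair separating beyond
        the maximum triggers replacement.
    max_angle_deg : float
        Largest accepted angular deviation of a replacement separation
        vector from the evolved one; the least-deviating candidate within
        the scale bounds is used, relaxing to the closest point when none
        qualifies.
    theiler : int, optional
        Temporal exclusion window (samples) around the reference point;
        defaults to one dominant period of the first coordinate.
    base : {"nats", "bits"}
        Logarithm base of the reported exponent.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim == 1:
        traj = traj[:, None]
    n = traj.shape[0]
    if n < _MIN_TRAJECTORY:
        raise AnalysisError(f"need >= {_MIN_TRAJECTORY} trajectory points, got {n}")
    if base not in ("nats", "bits"):
        raise AnalysisError("base must be 'nats' or 'bits'")
    if theiler is None:
        theiler = _dominant_period(traj[:, 0])

    centroid = traj.mean(axis=0)
    extent = float(np.sqrt(np.mean(np.sum((traj - centroid) ** 2, axis=1))))
    if extent == 0.0:
        raise AnalysisError("degenerate (constant) trajectory")
    d_min = min_scale_frac * extent
    d_max = max_scale_frac * extent

    tree = cKDTree(traj)

    def nearest_valid(i: int) -> int:
        k = 1
        while k < n:
            k = min(2 * k + 8, n)
            dist, idx = tree.query(traj[i], k=k)
            for cand, dc in zip(np.atleast_1d(idx), np.atleast_1d(dist)):
                if abs(cand - i) > theiler and cand + evolve < n and d_min < dc <= d_max:
                    return int(cand)
            if k == n:
                break
        return -1

    def replace(i: int, direction: np.ndarray) -> int:
        """Candidate near traj[i] minimizing angle to ``direction``."""
        cand = tree.query_ball_point(traj[i], d_max if d_max > 0 else extent)
        best, best_angle = -1, np.inf
        norm_dir = np.linalg.norm(direction)
        for j in cand:
            if abs(j - i) <= theiler or j + evolve >= n:
                continue
            vec = traj[j] - traj[i]
            dj = np.linalg.norm(vec)
            if dj <= d_min or dj == 0.0:
                continue
            cosang = np.clip(vec @ direction / (dj * norm_dir), -1, 1) \
                if norm_dir > 0 else 1.0
            ang = np.degrees(np.arccos(cosang))
            if ang < best_angle:
                best, best_angle = j, ang
        if best >= 0 and best_angle <= max_angle_deg:
            return best
        return best  # relax the angle constraint rather than abort

    i = 0
    j = nearest_valid(0)
    if j < 0:
        raise AnalysisError("no valid nearest neighbor within scale bounds")
    log_sum = 0.0
    total_time = 0.0
    d0s, d1s, times = [], [], []
    replacements = 0
    while i + evolve < n and j + evolve < n:
        d0 = float(np.linalg.norm(traj[i] - traj[j]))
        i2, j2 = i + evolve, j + evolve
        d1 = float(np.linalg.norm(traj[i2] - traj[j2]))
        if d0 > 0 and d1 > 0:
            log_sum += np.log(d1 / d0)
            seg_t = evolve / fs
            total_time += seg_t
            d0s.append(d0)
            d1s.append(d1)
            times.append(seg_t)
        i = i2
        j = j2
        if d1 > d_max or d1 == 0.0 or j + evolve >= n:
            direction = traj[j] - traj[i] if j < n else np.zeros(traj.shape[1])
            new_j = replace(i, direction)
            if new_j >= 0 and new_j != i:
                if new_j != j:
                    replacements += 1
                j = new_j
            elif j + evolve >= n:
                break
    if total_time == 0.0:
        raise AnalysisError("no usable evolution segments")
    lam = log_sum / total_time
    if base == "bits":
        lam /= np.log(2.0)
    return LleResult(
        lambda1=float(lam),
        units=f"{base}/s",
        spec=spec,
        d_initial=np.array(d0s),
        d_final=np.array(d1s),
        evolution_times=np.array(times),
        n_replacements=replacements,
    )


def lyapunov_exponent(x, fs: float, max_lag: int = 100, max_dim: int = 8,
                      **wolf_kwargs) -> LleResult:
    """AMI delay, FNN dimension, embedding, then Wolf's exponent."""
    x = np.asarray(x, dtype=float).ravel()
    ami = average_mutual_information(x, max_lag=max_lag)
    fnn = false_nearest_neighbors(x, tau=ami.tau, max_dim=max_dim)
    spec = EmbeddingSpec(tau=ami.tau, dim=fnn.dim)
    traj = delay_embed(x, spec)
    return wolf_lle(traj, fs=fs, spec=spec, **wolf_kwargs)
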