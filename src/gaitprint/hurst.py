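"""Bayesian Hurst-exponent estimation for stride series under the fGn model.

The observed series is modeled as x ~ N(mu * 1, sigma^2 * R(H)) where R(H)
is the fGn correlation matrix built from the closed-form autocorrelation
rho(k) = 1/2(|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}). The location mu and the
scale sigma are nuisance parameters: with the noninformative prior
p(mu, sigma^2) ∝ 1/sigma^2 both integrate out analytically, leaving the
marginal posterior of H under a uniform prior on (0, 1):

    log p(H | x) = -1/2 log|R| - 1/2 log(1' R^-1 1)
                   - (n-1)/2 log( x' R^-1 x - (1' R^-1 x)^2 / (1' R^-1 1) )

up to a constant. The Toeplitz quadratic forms and log-determinant are
computed in O(n^2) by a Levinson-Durbin innovations recursion (numba-
compiled), which keeps full trials of >2,000 strides tractable. The
posterior is evaluated on an adaptive H grid (coarse scan refined to step
0.001 around the mass region); the point estimate is the posterior median.

This marginal-likelihood route makes the estimate exactly invariant to
affine transforms of the input and behaves well on short series, which is
what stride-interval analysis needs: a four-minute trial yields only
~220 strides per foot.

A shuffle surrogate (random permutation) destroys temporal ordering while
preserving the amplitude distribution; re-estimating H on the surrogate
should return ~0.5 if the original estimate reflected genuine long-range
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import AnalysisError

__all__ = ["HurstResult", "estimate_hurst", "shuffle_surrogate"]


@dataclass(frozen=True)
class HurstResult:
    """Posterior summary of the Hurst exponent of one series."""

    h: float                 # posterior median
    ci_low: float            # 2.5% posterior quantile
    ci_high: float           # 97.5% posterior quantile
    n: int                   # series length used
    grid: np.ndarray         # H values where the posterior was evaluated
    log_posterior: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 < self.h < 1.0:
            raise AnalysisError(f"H estimate {self.h} outside (0, 1)")
        if not self.ci_low <= self.h <= self.ci_high:
            raise AnalysisError("credible interval does not contain the estimate")


@njit(cache=True)
def _log_marginal_grid(x: np.ndarray, hs: np.ndarray) -> np.ndarray:  # pragma: no cover
    """Log marginal posterior of H (up to a constant) at each grid value.

    For each H: Levinson-Durbin recursion on the fGn autocorrelation giving
    prediction coefficients, innovation variances (-> log|R|), and whitened
    versions of x and of the ones vector (-> the three quadratic forms).
    """
    n = x.shape[0]
    out = np.empty(hs.shape[0])
    rho = np.empty(n)
    phi = np.zeros(n)
    phi_prev = np.zeros(n)
    for gi in range(hs.shape[0]):
        h = hs[gi]
        two_h = 2.0 * h
        rho[0] = 1.0
        for k in range(1, n):
            rho[k] = 0.5 * ((k + 1.0) ** two_h - 2.0 * k ** two_h
                            + (k - 1.0) ** two_h)
        for j in range(n):
            phi[j] = 0.0
            phi_prev[j] = 0.0
        e_var = 1.0
        logdet = 0.0
        qxx = x[0] * x[0]
        q11 = 1.0
        qx1 = x[0]
        for tt in range(1, n):
            acc = rho[tt]
            for j in range(1, tt):
                acc -= phi_prev[j] * rho[tt - j]
            kappa = acc / e_var
            phi[tt] = kappa
            for j in range(1, tt):
                phi[j] = phi_prev[j] - kappa * phi_prev[tt - j]
            e_var = e_var * (1.0 - kappa * kappa)
            if e_var <= 0.0:
                e_var = 1e-300
            pred_x = 0.0
            pred_1 = 0.0
            for j in range(1, tt + 1):
                pred_x += phi[j] * x[tt - j]
                pred_1 += phi[j]
            ex = x[tt] - pred_x
            e1 = 1.0 - pred_1
            qxx += ex * ex / e_var
            q11 += e1 * e1 / e_var
            qx1 += ex * e1 / e_var
            logdet += np.log(e_var)
            for j in range(1, tt + 1):
                phi_prev[j] = phi[j]
        s2 = qxx - qx1 * qx1 / q11
        if s2 <= 0.0:
            s2 = 1e-300
        out[gi] = -0.5 * logdet - 0.5 * np.log(q11) - 0.5 * (n - 1.0) * np.log(s2)
    return out


def _posterior_summary(grid: np.ndarray, logpost: np.ndarray) -> tuple[float, float, float]:
    """Median and central 95% interval from log-density values on a grid."""
    lp = logpost - logpost.max()
    dens = np.exp(lp)
    cdf = np.concatenate([[0.0], np.cumsum(
        0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))])
    total = cdf[-1]
    if total <= 0:
        raise AnalysisError("degenerate posterior")
    cdf /= total
    med = float(np.interp(0.5, cdf, grid))
    lo = float(np.interp(0.025, cdf, grid))
    hi = float(np.interp(0.975, cdf, grid))
    return med, lo, hi


def estimate_hurst(x, coarse_step: float = 0.01, fine_step: float = 0.001,
                   log_window: float = 12.0) -> HurstResult:
    """Estimate the Hurst exponent of a series under the fGn model.

    Parameters
    ----------
    x : array-like
        Series of length >= 64, finite, non-constant. Location and scale are
        handled by the likelihood; no preprocessing is needed.
    coarse_step, fine_step : float
        Grid resolutions of the two-stage posterior scan over H in (0, 1).
    log_window : float
        Coarse grid points within this many log units of the maximum define
        the region refined at ``fine_step``.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 64:
        raise AnalysisError(f"need at least 64 samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise AnalysisError("series contains non-finite values")
    if np.ptp(x) == 0.0:
        raise AnalysisError("series is constant")
    # Standardize for numerical conditioning only (the marginal likelihood is
    # affine invariant, so this does not change the posterior).
    xs = (x - x.mean()) / x.std()

    coarse = np.arange(coarse_step, 1.0, coarse_step)
    lp_coarse = _log_marginal_grid(xs, coarse)
    keep = lp_coarse >= lp_coarse.max() - log_window
    lo = max(fine_step, coarse[keep].min() - 2 * coarse_step)
    hi = min(1.0 - fine_step, coarse[keep].max() + 2 * coarse_step)
    fine = np.arange(lo, hi + fine_step / 2, fine_step)
    lp_fine = _log_marginal_grid(xs, fine)

    med, ci_lo, ci_hi = _posterior_summary(fine, lp_fine)
    return HurstResult(h=med, ci_low=ci_lo, ci_high=ci_hi, n=x.size,
                       grid=fine, log_posterior=lp_fine)


def shuffle_surrogate(x, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Random permutation of a series (order destroyed, amplitudes kept).

    Deterministic given an integer seed.
    """
    x = np.asarray(x).ravel()
    if x.size < 2:
        raise AnalysisError("need at least 2 samples to shuffle")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return rng.permutation(x)
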