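"""Delay reconstruction (AMI/FNN) and Wolf exponent vs independent oracles."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from gaitprint import (
    EmbeddingSpec,
    average_mutual_information,
    delay_embed,
    false_nearest_neighbors,
    wolf_lle,
)
from gaitprint.errors import AnalysisError


def benettin_lorenz_lambda1(dt=0.002, n_steps=150_000, transient=20_000):
    """Largest Lyapunov exponent of the Lorenz system (sigma=10, rho=28,
    beta=8/3) by integrating the variational equations with RK4 and
    renormalizing the tangent vector each step. Independent of any
    trajectory-based estimator."""
    sigma, rho, beta = 10.0, 28.0, 8.0 / 3.0

    def deriv(s):
        x, y, z, dx, dy, dz = s
        return np.array([
            sigma * (y - x),
            x * (rho - z) - y,
            x * y - beta * z,
            sigma * (dy - dx),
            dx * (rho - z) - dy - x * dz,
            dx * y + x * dy - beta * dz,
        ])

    s = np.array([1.0, 1.0, 20.0, 1.0, 0.0, 0.0])
    log_sum = 0.0
    for step in range(n_steps):
        k1 = deriv(s)
        k2 = deriv(s + 0.5 * dt * k1)
        k3 = deriv(s + 0.5 * dt * k2)
        k4 = deriv(s + dt * k3)
        s = s + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        norm = np.linalg.norm(s[3:])
        s[3:] /= norm
        if step >= transient:
            log_sum += np.log(norm)
    return log_sum / ((n_steps - transient) * dt)


class TestAmi:
    def test_lag_zero_is_marginal_entropy(self):
        x = np.random.default_rng(0).standard_normal(10_000)
        res = average_mutual_information(x, max_lag=20, bins=16)
        # equiprobable 16 bins -> 4 bits of self-information
        assert res.ami[0] == pytest.approx(4.0, abs=0.01)
        assert res.ami[0] == res.ami.max()

    def test_iid_noise_has_no_lagged_information(self):
        x = np.random.default_rng(1).standard_normal(10_000)
        res = average_mutual_information(x, max_lag=10, bins=16)
        assert res.ami[1:].max() < 0.05

    def test_sinusoid_first_minimum_near_quarter_period(self):
        # measurement noise regularizes the degenerate noise-free histogram
        rng = np.random.default_rng(2)
        x = np.sin(2 * np.pi * np.arange(12_000) / 100.0) \
            + 0.05 * rng.standard_normal(12_000)
        res = average_mutual_information(x, max_lag=45)
        assert res.tau == pytest.approx(25, abs=2)

    def test_constant_rejected(self):
        with pytest.raises(AnalysisError):
            average_mutual_information(np.ones(5000), max_lag=10)


class TestFnn:
    def test_sinusoid_needs_two_dimensions(self):
        x = np.sin(2 * np.pi * np.arange(20_000) / 200.0)
        res = false_nearest_neighbors(x, tau=50, max_dim=5)
        assert res.dim == 2
        assert res.fractions[1] < 0.01

    def test_lorenz_needs_three_dimensions(self, lorenz_x):
        res = false_nearest_neighbors(lorenz_x, tau=20, max_dim=6)
        assert res.dim == 3

    def test_too_short_series_rejected(self):
        with pytest.raises(AnalysisError):
            false_nearest_neighbors(np.sin(np.arange(100.0)), tau=10,
                                    max_dim=10)


class TestDelayEmbed:
    def test_row_count_formula(self):
        traj = delay_embed(np.arange(10.0), EmbeddingSpec(tau=2, dim=3))
        assert traj.shape == (6, 3)

    def test_dim_one_is_identity(self):
        x = np.arange(25.0)
        traj = delay_embed(x, EmbeddingSpec(tau=3, dim=1))
        np.testing.assert_array_equal(traj.ravel(), x)

    def test_quarter_period_embedding_traces_circle(self):
        x = np.sin(2 * np.pi * np.arange(4000) / 200.0)
        traj = delay_embed(x, EmbeddingSpec(tau=50, dim=2))
        radii = np.hypot(traj[:, 0], traj[:, 1])
        assert np.ptp(radii) / radii.mean() < 0.01


@pytest.fixture(scope="module")
def sin_traj():
    x = np.sin(2 * np.pi * 1.0 * np.arange(20_000) / 200.0)
    return delay_embed(x, EmbeddingSpec(tau=50, dim=2))


class TestWolf:
    def test_periodic_orbit_has_zero_exponent(self, sin_traj):
        res = wolf_lle(sin_traj, fs=200.0)
        assert abs(res.lambda1) < 0.05
        assert res.units == "nats/s"

    def test_exact_scale_invariance(self, sin_traj):
        a = wolf_lle(sin_traj, fs=200.0).lambda1
        b = wolf_lle(2.0 * sin_traj, fs=200.0).lambda1
        assert a == b

    def test_translation_invariance(self, sin_traj):
        a = wolf_lle(sin_traj, fs=200.0).lambda1
        b = wolf_lle(sin_traj + 3.0, fs=200.0).lambda1
        assert b == pytest.approx(a, abs=1e-9)

    def test_bits_option(self, sin_traj):
        nats = wolf_lle(sin_traj, fs=200.0).lambda1
        bits = wolf_lle(sin_traj, fs=200.0, base="bits").lambda1
        assert bits == pytest.approx(nats / np.log(2.0), abs=1e-12)

    def test_lorenz_agrees_with_benettin_oracle(self, lorenz_x):
        oracle = benettin_lorenz_lambda1()
        assert oracle == pytest.approx(0.906, abs=0.03)  # literature value
        traj = delay_embed(lorenz_x, EmbeddingSpec(tau=20, dim=3))
        res = wolf_lle(traj, fs=100.0)
        assert res.lambda1 == pytest.approx(oracle, rel=0.15)

    def test_noise_increases_divergence_monotonically(self):
        """lambda1 of noisy sinusoids rises with noise amplitude."""
        levels = [0.01, 0.03, 0.1, 0.3, 1.0]
        lams = np.empty((5, 20))
        for i, level in enumerate(levels):
            for s in range(20):
                rng = np.random.default_rng(1000 * i + s)
                x = np.sin(2 * np.pi * np.arange(6000) / 200.0) \
                    + level * rng.standard_normal(6000)
                traj = delay_embed(x, EmbeddingSpec(tau=50, dim=2))
                lams[i, s] = wolf_lle(traj, fs=200.0).lambda1
        rho, _ = spearmanr(np.repeat(levels, 20), lams.ravel())
        assert rho > 0.9

    def test_short_trajectory_rejected(self):
        with pytest.raises(AnalysisError):
            wolf_lle(np.random.default_rng(0).standard_normal((100, 2)),
                     fs=100.0)
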