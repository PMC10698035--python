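import numpy as np
import pytest

from gaitprint import (
    TrialConfig,
    detect_gait_events,
    simulate_trial,
    standard_channel_map,
)


@pytest.fixture(scope="session")
def channel_map():
    return standard_channel_map()


@pytest.fixture(scope="session")
def standard_trial():
    """Full four-minute noise-free trial with its ground truth."""
    return simulate_trial(TrialConfig(seed=11))


@pytest.fixture(scope="session")
def standard_events(standard_trial, channel_map):
    trial, _ = standard_trial
    return detect_gait_events(trial, channel_map)


@pytest.fixture(scope="session")
def short_trial():
    """One-minute noise-free trial: fast to generate, ~54 strides."""
    return simulate_trial(TrialConfig(duration_s=60.0, seed=7))


@pytest.fixture(scope="session")
def lorenz_x():
    """x-component of the standard Lorenz system, dt = 0.01, transient cut."""
    from scipy.integrate import solve_ivp

    def lorenz(t, s):
        x, y, z = s
        return [10.0 * (y - x), x * (28.0 - z) - y, x * y - (8.0 / 3.0) * z]

    sol = solve_ivp(lorenz, (0.0, 320.0), [1.0, 1.0, 20.0],
                    t_eval=np.arange(20.0, 320.0, 0.01),
                    rtol=1e-9, atol=1e-9)
    return sol.y[0]
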