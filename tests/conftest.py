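import numpy as np
import pytest

import repsync as rs


def brute_force_autocorrelation(x, max_lag):
    """Direct truncated-sum evaluation of the normalized autocorrelation.

    Mean-centers the series, computes the lag-k product sum over the
    overlapping samples l = 0..N-1-k, and normalizes by the lag-0 sum.
    Independent oracle for the FFT implementation.
    """
    x = np.asarray(x, dtype=float)
    xb = x - x.mean()
    denom = float(np.dot(xb, xb))
    n = len(x)
    return np.array([float(np.dot(xb[: n - k], xb[k:])) / denom
                     for k in range(max_lag + 1)])


@pytest.fixture(scope="session")
def cosine_series():
    """cos(2*pi*t/10) sampled at dt=0.1 over exactly 40 periods."""
    dt = 0.1
    t = np.arange(4000) * dt
    return t, np.cos(2 * np.pi * t / 10.0), dt


@pytest.fixture(scope="session")
def two_tone_series():
    dt = 0.1
    t = np.arange(4000) * dt
    x = np.cos(2 * np.pi * t / 10.0) + np.cos(2 * np.pi * t / 4.0)
    return t, x, dt


@pytest.fixture(scope="session")
def short_coupled_traj():
    """A short coupled simulation in an oscillatory regime (γ=0.5, K=1)."""
    params = rs.build_params(0.5, 1.0, 1.0)
    config = rs.SimConfig(t_end=400.0, dt=0.05, t_burn=50.0, seed=11)
    traj = rs.integrate(params, config)
    return rs.discard_transient(traj, config.t_burn)


@pytest.fixture(scope="session")
def quick_sim_config():
    return rs.SimConfig(t_end=250.0, dt=0.05, t_burn=50.0, seed=3)
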