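import numpy as np
import pytest

from epileptornet.dynamics import ModelParams, Trajectory, integrate


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def oscillatory_traj(params):
    """Long isolated run well above threshold: periodic seizure cycling."""
    return integrate(params, -1.6, record_every=10)


@pytest.fixture(scope="session")
def quiescent_traj(params):
    """Long isolated run well below threshold: relaxation to a fixed point."""
    return integrate(params, -2.5, record_every=10)


@pytest.fixture
def constant_traj():
    times = np.arange(200.0)
    states = np.tile([-1.6, -10.0, 3.0, -0.6, 0.0, 0.0], (200, 1))
    return Trajectory(times=times, states=states, dt=1.0)


def square_wave(n_cycles=3, low=-1.6, high=0.5, half=400, lead=400, tail=400):
    """Synthetic x1 alternating `half` units high / `half` units low."""
    parts = [np.full(lead, low)]
    for _ in range(n_cycles):
        parts.append(np.full(half, high))
        parts.append(np.full(half, low))
    parts.append(np.full(tail, low))
    x1 = np.concatenate(parts)
    return np.arange(len(x1), dtype=float), x1
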