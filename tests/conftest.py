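import numpy as np
import pytest

from spatialtuning.session import SessionRecording, SpikeTrain, Trajectory
from spatialtuning.synthetic import build_geometry, simulate_trajectory


@pytest.fixture(scope="session")
def octagon():
    return build_geometry("octagon")


@pytest.fixture(scope="session")
def traj1200(octagon):
    """Shared 20 min octagon foraging run at 50 Hz."""
    return simulate_trajectory(octagon, 1200.0, seed=424242)


@pytest.fixture(scope="session")
def traj600(octagon):
    return simulate_trajectory(octagon, 600.0, seed=31337)


def make_session(traj, spikes, geometry, **kw):
    if isinstance(spikes, SpikeTrain):
        spikes = [spikes]
    return SessionRecording(trajectory=traj, spikes=spikes, geometry=geometry, **kw)


@pytest.fixture
def straight_trajectory():
    """Constant 10 cm/s motion along +x at 50 Hz, centered on the origin."""
    t = np.arange(200) * 0.02
    x = -20.0 + 10.0 * t
    return Trajectory(times=t, x=x, y=np.zeros_like(t), heading=np.zeros_like(t))


@pytest.fixture
def stationary_trajectory():
    t = np.arange(500) * 0.02
    z = np.zeros_like(t)
    return Trajectory(times=t, x=z + 3.0, y=z - 2.0, heading=z + 45.0)
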