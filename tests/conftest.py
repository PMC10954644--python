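import numpy as np
import pytest

from hogrc.reservoir import ReservoirConfig
from hogrc.systems import Trajectory, rk4_integrate, simulate


@pytest.fixture(scope="session")
def lorenz_traj() -> Trajectory:
    """A moderately long Lorenz63 trajectory for unit tests."""
    return simulate("lorenz63", steps=2000, transient=500, seed=11)


@pytest.fixture(scope="session")
def small_cfg() -> ReservoirConfig:
    """A small reservoir configuration keeping unit tests fast."""
    return ReservoirConfig(n=60, washout=20, seed=7)


@pytest.fixture(scope="session")
def decoupled_traj() -> Trajectory:
    """Two independent harmonic oscillators: no cross-variable structure.

    Variables (a, b) and (c, d) form two uncoupled linear subsystems with
    incommensurate frequencies, so the ground-truth structure never links
    the pairs and the signal persists over the whole window.
    """

    def field(s):
        a, b, c, d = s
        return np.array([b, -a, 2.3 * d, -2.3 * c])

    return rk4_integrate(field, [1.0, 0.0, 0.0, 1.5], 0.05, 1500, names=list("abcd"))
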