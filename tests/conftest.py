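"""Shared fixtures: small deterministic datasets reused across tests."""

import numpy as np
import pytest

from scribblekit import synthgen
from scribblekit.kinematics import Trajectory


@pytest.fixture(scope="session")
def parabola_traj() -> Trajectory:
    """Noiseless constant-acceleration parabola sampled at 100 Hz."""
    t = np.arange(0.0, 2.0, 0.01)
    v0, a = np.array([120.0, 40.0]), np.array([-60.0, 90.0])
    x = v0[0] * t + 0.5 * a[0] * t ** 2
    y = v0[1] * t + 0.5 * a[1] * t ** 2
    return Trajectory(t=t, x=x, y=y)


@pytest.fixture(scope="session")
def scribble():
    """Short noiseless parabolic scribble (trajectory + ground truth)."""
    spec = synthgen.velocity_cycle_spec(n_segments=40, seed=7)
    return synthgen.gen_parabolic_scribble(spec)


@pytest.fixture(scope="session")
def scribble_traj(scribble) -> Trajectory:
    return scribble[0]
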