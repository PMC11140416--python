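import numpy as np
import pytest

from glecell import KernelParams, kernel_to_embedding, simulate
from glecell.trajectory_io import Trajectory

#: reference parameter set used across the suite: a typical fast swimmer
P_STD = KernelParams(a=5.0, b=2000.0, tau=0.5, omega=120.0)
B_STD = 1000.0
DT = 0.002


@pytest.fixture(scope="session")
def p_std() -> KernelParams:
    return P_STD


@pytest.fixture(scope="session")
def sim_medium():
    """One medium-length simulated cell (N=2e5) with its true velocities."""
    e = kernel_to_embedding(P_STD, B_STD)
    traj, vel = simulate(e, 200_000, DT, seed=20240321, return_velocities=True)
    return traj, vel, e


def make_trajectory(x, y=None, dt=DT, cell_id="t") -> Trajectory:
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    times = np.arange(len(x)) * dt
    return Trajectory(cell_id=cell_id, times=times, x=x, y=y, dt=dt)
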