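import numpy as np
import pytest

from openarena.core import SessionConfig, Trajectory
from openarena.preprocess import derive_kinematics
from openarena.synth import CellSpec, make_session


@pytest.fixture(scope="session")
def cfg600():
    return SessionConfig(trial_duration=600.0, rng_seed=1)


@pytest.fixture(scope="session")
def mixed_session(cfg600):
    """One 10-min session with one cell of every class (shared, read-only)."""
    specs = [
        CellSpec(kind="place", peak_rate=12.0, field_sigma=8.0, field_center=(30.0, 30.0)),
        CellSpec(kind="grid", peak_rate=15.0, grid_spacing=30.0, field_center=(10.0, 10.0)),
        CellSpec(kind="hd", peak_rate=15.0, hd_mu=90.0, hd_kappa=4.0),
        CellSpec(kind="speed", baseline_rate=2.0, speed_slope=0.2),
        CellSpec(kind="uniform", peak_rate=3.0),
    ]
    s = make_session(cfg600, specs, seed=101)
    for c in s.cells:
        c.annotate(s.trajectory)
    return s


def straight_trajectory(
    speed=12.0, duration=60.0, rate=50.0, start=(5.0, 30.0), direction=0.0
):
    """Constant-velocity path (no walls), with kinematics derived."""
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    th = np.deg2rad(direction)
    x = start[0] + speed * t * np.cos(th)
    y = start[1] + speed * t * np.sin(th)
    traj = Trajectory(t=t, x=x, y=y, hd=np.full(n, direction % 360.0))
    return derive_kinematics(traj)


@pytest.fixture
def make_straight():
    return straight_trajectory
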