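import numpy as np
import pytest

from spineneck import NeckGeometry, SimulationConfig
from spineneck.spt import Trajectory


@pytest.fixture
def geom() -> NeckGeometry:
    """Default neck: 66/105/195 nm domains on a 1 um axis along x."""
    return NeckGeometry()


@pytest.fixture
def no_sp_geom() -> NeckGeometry:
    return NeckGeometry(outer_diameter=105.0, actin_diameter=105.0,
                        sp_diameter=66.0, sp_segment=None)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_trajectory(xy: np.ndarray, dt: float = 0.012, traj_id: int = 0
                    ) -> Trajectory:
    xy = np.asarray(xy, float)
    return Trajectory(traj_id=traj_id, frames=np.arange(len(xy)), xy=xy, dt=dt)


def brute_force_msd(xy: np.ndarray, dimensionality: int = 2,
                    axis: np.ndarray | None = None) -> np.ndarray:
    """Independent double-loop MSD used as the oracle for compute_msd."""
    n_pts = len(xy)
    out = np.empty(n_pts - 1)
    for n in range(1, n_pts):
        acc = 0.0
        for i in range(n_pts - n):
            dx = xy[i + n, 0] - xy[i, 0]
            dy = xy[i + n, 1] - xy[i, 1]
            if dimensionality == 2:
                acc += dx * dx + dy * dy
            else:
                proj = dx * axis[0] + dy * axis[1]
                acc += proj * proj
        out[n - 1] = acc / (n_pts - n)
    return out
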