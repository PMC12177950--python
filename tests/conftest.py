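import numpy as np
import pytest

from trapdiff.trajectories import Trajectory, TrajectorySet


def brownian_trajectory(rng, n, D, dt, track_id=0, origin=(0.0, 0.0)):
    """Unconfined 2D Brownian track: increments N(0, 2 D dt) per axis."""
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n - 1, 2))
    pos = np.vstack([[origin], origin + np.cumsum(steps, axis=0)])
    return Trajectory(track_id=track_id, frames=np.arange(n),
                      x=pos[:, 0], y=pos[:, 1], frame_time=dt)


def brownian_set(rng, n_tracks, n, D, dt):
    trajs = [brownian_trajectory(rng, n, D, dt, track_id=i) for i in range(n_tracks)]
    return TrajectorySet(trajs, frame_time=dt)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def simple_track():
    """Positions (0,0), (1,0), (1,1) um at 0.1 s frame time."""
    return Trajectory(track_id=0, frames=[0, 1, 2], x=[0.0, 1.0, 1.0],
                      y=[0.0, 0.0, 1.0], frame_time=0.1)
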