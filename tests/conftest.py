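import numpy as np
import pytest

from wormfeatures.io import WormTrajectory


def make_trajectory(points, fps=25.0, **kwargs):
    """WormTrajectory from a (T, P, 2) array with uniform timestamps."""
    points = np.asarray(points, dtype=float)
    times = np.arange(points.shape[0]) / fps
    return WormTrajectory(
        kwargs.pop("worm_id", "w"), points, times, fps=fps, **kwargs
    )


def straight_skeleton(n_points=49, spacing=20.0, n_frames=3):
    pts = np.zeros((n_frames, n_points, 2))
    pts[:, :, 0] = np.arange(n_points) * spacing
    return pts


@pytest.fixture
def straight_worm():
    """Motionless straight worm: 49 points spaced 20 um, length 960 um."""
    return make_trajectory(straight_skeleton())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
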