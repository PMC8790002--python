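import numpy as np
import pytest

from livreg.grid import Image3D, LabelMap3D, VolumeGrid
from livreg.phantom import AffineMagnitude, PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def small_study():
    """One 32-cube synthetic study shared by fast tests."""
    cfg = PhantomConfig(
        grid_shape=(32, 32, 32), n_landmarks=2, landmark_radius_mm=6.0,
        affine_magnitude=AffineMagnitude(10.0, 5.0, 0.05),
        warp_amplitude_mm=5.0, seed=2,
    )
    return generate_phantom(cfg)


@pytest.fixture
def unit_grid():
    return VolumeGrid((8, 8, 8), (1.0, 1.0, 1.0))


@pytest.fixture
def ramp_image(unit_grid):
    xs = np.arange(8, dtype=float)
    vals = np.broadcast_to(xs[:, None, None], (8, 8, 8)).copy()
    return Image3D(unit_grid, vals)


def make_mask(grid: VolumeGrid, predicate) -> LabelMap3D:
    """Binary mask from a world-coordinate predicate."""
    pts = grid.world_points()
    return LabelMap3D(grid, predicate(pts).astype(np.uint8))
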