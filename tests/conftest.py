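import numpy as np
import pytest
from hypothesis import settings

import gliodensity as gd

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom96():
    """Default analysis phantom: 96^3 voxels at 0.5 mm, 5 mm core."""
    return gd.make_brain_phantom(seed=0)


@pytest.fixture(scope="session")
def distance96(phantom96):
    """Geodesic distance to the core through white matter (mm)."""
    return gd.geodesic_distance(
        phantom96.core_mask, phantom96.white_mask, grid=phantom96.grid
    )


@pytest.fixture(scope="session")
def domain96(phantom96):
    return phantom96.white_mask | phantom96.core_mask


@pytest.fixture(scope="session")
def phantom48():
    """Small phantom for cheaper tests (24 mm box, 2 mm core)."""
    return gd.make_brain_phantom(shape=(48, 48, 48), core_radius_mm=2.0, seed=0)


def white_rod(n: int, dx: float):
    """Quasi-1D all-white rod along the last axis."""
    from gliodensity.grids import LABELS, TissueLabelVolume, VoxelGrid

    labels = np.full((1, 1, n), LABELS["white"], dtype=np.uint8)
    return TissueLabelVolume(VoxelGrid((1, 1, n), (dx, dx, dx)), labels)
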