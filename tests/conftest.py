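import numpy as np
import pytest

from mcspect import (
    AcquisitionProtocol,
    SystemModel,
    VoxelVolume,
    make_cylinder_attenuation,
    make_grid,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_grid():
    """16x16x8 grid of 4.42 mm voxels."""
    return make_grid(16, 8, 4.42)


@pytest.fixture
def small_system():
    return SystemModel(pixel_size_mm=4.42, matrix=(16, 16))


@pytest.fixture
def small_protocol():
    return AcquisitionProtocol(n_projections=8, orbit_radius_mm=150.0)


@pytest.fixture
def water_cylinder(small_grid):
    return make_cylinder_attenuation(30.0, 60.0, small_grid, "water", 171.0)


@pytest.fixture
def random_volume(small_grid, rng):
    return VoxelVolume(rng.random(small_grid.shape), small_grid.spacing)
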