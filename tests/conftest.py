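import numpy as np
import pytest

from iftomo import OpticalProperties, ScanGeometry, VoxelGrid


@pytest.fixture(scope="session")
def tissue_props() -> OpticalProperties:
    """Standard slab optical properties used across the suite."""
    return OpticalProperties(mu_s=20.0, mu_a=0.1, g=0.85)


@pytest.fixture(scope="session")
def small_grid() -> VoxelGrid:
    return VoxelGrid(extent=(2.5, 2.5, 1.5), voxel_size=(0.25, 0.25, 0.1))


@pytest.fixture(scope="session")
def small_geometry() -> ScanGeometry:
    return ScanGeometry(fov=(2.5, 2.5), scan_step=0.25)


@pytest.fixture(scope="session")
def mc_fluence(tissue_props):
    """One shared Monte-Carlo run on the standard slab (2e5 photons)."""
    from iftomo import run_mc

    grid = VoxelGrid(extent=(4.0, 4.0, 2.0), voxel_size=(0.25, 0.25, 0.1))
    fm = run_mc(tissue_props, grid, (2.0, 2.0), photons=200_000, seed=3)
    return grid, fm


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
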