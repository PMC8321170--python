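import numpy as np
import pytest

from petas3d.phantom import PhantomSpec, generate_phantom
from petas3d.volume_io import BinaryMask, Grid3D, SUVVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return Grid3D((8, 8, 8), (1.0, 1.0, 1.0))


@pytest.fixture
def aniso_grid():
    return Grid3D((16, 16, 12), (2.73, 2.73, 3.27))


@pytest.fixture(scope="session")
def clean_sphere():
    """Noiseless, blur-free sphere phantom on a small grid (exact two-valued image)."""
    spec = PhantomSpec(
        grid=Grid3D((32, 32, 32), (1.0, 1.0, 1.0)),
        radius_mm=10.0,
        noise_sigma=0.0,
        psf_fwhm_mm=0.0,
        seed=0,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def default_sphere():
    """Sphere phantom at the default study conditions (64x64x48, 8:1, 5% noise)."""
    return generate_phantom(PhantomSpec(seed=7))


def random_mask(grid: Grid3D, rng, p=0.3) -> BinaryMask:
    vals = (rng.random(grid.shape) < p).astype(np.uint8)
    return BinaryMask(grid, vals)


def random_volume(grid: Grid3D, rng) -> SUVVolume:
    return SUVVolume(grid, rng.random(grid.shape) * 5.0)
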