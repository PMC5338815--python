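import numpy as np
import pytest

from morphodist.volumes import Grid, ImageVolume


@pytest.fixture(scope="session")
def grid16():
    return Grid((16, 16, 16))


@pytest.fixture(scope="session")
def grid32():
    return Grid((32, 32, 32))


def gaussian_blob(dims, center, sigma=4.0):
    """Smooth blob image used as a registration target."""
    coords = np.mgrid[0 : dims[0], 0 : dims[1], 0 : dims[2]].astype(np.float64)
    r2 = sum((coords[i] - center[i]) ** 2 for i in range(3))
    return np.exp(-r2 / (2 * sigma**2))


@pytest.fixture(scope="session")
def blob_pair(grid32):
    """Fixed blob at the centre, moving blob displaced 3 voxels along x."""
    fixed = ImageVolume(gaussian_blob((32, 32, 32), (16, 16, 16)), grid32)
    moving = ImageVolume(gaussian_blob((32, 32, 32), (13, 16, 16)), grid32)
    return fixed, moving


def smooth_vector_field(rng, dims, amplitude, sigma=1.5):
    """Random smooth vector field with given max per-component amplitude."""
    from scipy import ndimage

    f = rng.standard_normal(dims + (3,))
    for i in range(3):
        f[..., i] = ndimage.gaussian_filter(f[..., i], sigma, mode="nearest")
    return f * (amplitude / np.abs(f).max())
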