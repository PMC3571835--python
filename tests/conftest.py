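import numpy as np
import pytest

from hyperseed import synthetic
from hyperseed.hypercube_io import Hypercube, ROI


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_cube(rng, rows=4, cols=5, bands=6, kind="raw", dtype=np.float32):
    data = rng.random((rows, cols, bands)).astype(dtype)
    wl = 400.0 + 10.0 * np.arange(bands)
    return Hypercube(data, wl, kind=kind)


@pytest.fixture()
def small_cube(rng):
    return make_cube(rng)


def reflectance_roi(data, wavelengths=None):
    """Wrap a (side x side x bands) array as a reflectance ROI."""
    data = np.asarray(data, dtype=float)
    side = data.shape[0]
    wl = (
        np.asarray(wavelengths, dtype=float)
        if wavelengths is not None
        else 500.0 + np.arange(data.shape[2], dtype=float)
    )
    return ROI(Hypercube(data, wl, kind="reflectance"), (0, 0), side)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small six-variety dataset shared by module tests (16x16x32 cubes)."""
    return synthetic.generate_dataset(4, side=16, bands=32, seed=7)
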