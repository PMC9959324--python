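import numpy as np
import pytest

from hsipatho.hsi_io import HyperspectralCube, WavelengthGrid


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_cube(rng):
    """A 16 x 12 cube with 8 bands of calibrated values in [0, 1]."""
    values = rng.random((16, 12, 8)).astype(np.float32)
    grid = WavelengthGrid(np.linspace(400.0, 800.0, 8))
    return HyperspectralCube(values=values, wavelengths=grid, calibrated=True)


def make_cube(values, lo=400.0, hi=800.0, calibrated=False):
    values = np.asarray(values)
    grid = WavelengthGrid(np.linspace(lo, hi, values.shape[2]))
    return HyperspectralCube(values=values, wavelengths=grid, calibrated=calibrated)
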