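import numpy as np
import pytest

import duospec as ds
from duospec.workflows import build_system, calibrate_all, select_all


@pytest.fixture(scope="session")
def system():
    """Default binary system with noiseless calibration series."""
    return build_system()


@pytest.fixture(scope="session")
def method_specs(system):
    """Selected working wavelengths for all six (analyte, method) pairs."""
    return select_all(system)


@pytest.fixture(scope="session")
def calibrations(system, method_specs):
    """Noiseless fitted calibration models for all six pairs."""
    return calibrate_all(system, method_specs)


@pytest.fixture
def gaussian_spectrum():
    """A single Gaussian band on the default grid (analytic oracle handy)."""
    grid = ds.default_grid()
    center, sigma = 250.0, 7.0
    values = np.exp(-((grid - center) ** 2) / (2 * sigma**2))
    return ds.Spectrum(grid, values, label="gaussian"), center, sigma


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
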