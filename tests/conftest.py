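import numpy as np
import pytest

from phenopine.fluorescence import default_protocol
from phenopine.spectra import Spectrum
from phenopine.synthetic import (
    EndmemberModel,
    generate_background_spectrum,
    generate_endmember_spectrum,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def grid_small():
    """Coarse wavelength grid that still contains every index band."""
    return np.arange(350.0, 2501.0, 1.0)


@pytest.fixture(scope="session")
def endmember(grid_small):
    return generate_endmember_spectrum(EndmemberModel(), grid_small)


@pytest.fixture(scope="session")
def background(grid_small):
    return generate_background_spectrum(grid_small)


@pytest.fixture
def flat_spectrum():
    def make(value, wavelengths=None):
        wl = np.arange(350.0, 801.0) if wavelengths is None else np.asarray(wavelengths)
        return Spectrum(wl, np.full(wl.size, float(value)))

    return make
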