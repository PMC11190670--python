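import warnings

import pytest

from thermoblock.membrane import MembraneParams
from thermoblock.synth import make_fixture_axons

# temperature-extrapolation warnings are expected in block protocols
warnings.filterwarnings("ignore", message="temperatures above 25 degC")


@pytest.fixture(scope="session")
def fixtures():
    """Catalog of short, coarse-grid axons for fast end-to-end tests."""
    return make_fixture_axons()


@pytest.fixture(scope="session")
def params():
    return MembraneParams()


@pytest.fixture(scope="session")
def params_original():
    return MembraneParams.original()
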