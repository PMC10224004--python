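import pytest
from hypothesis import settings

from partisol import SoluteSpec, SolventSpec
from partisol.io import load_packaged_table

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

# printed van't Hoff coefficients for iproniazid
OCTANOL_AB = (5.79, -2469.0)
HEXANE_AB = (7.28, -4809.0)
FIVE_TEMPS = [290.2, 293.2, 298.2, 303.2, 310.2]


@pytest.fixture(scope="session")
def ipn():
    return SoluteSpec("IPN", 179.22)


@pytest.fixture(scope="session")
def octanol():
    return SolventSpec("1-octanol", 130.23, 0.8262)


@pytest.fixture(scope="session")
def hexane():
    return SolventSpec("n-hexane", 86.18, 0.6548)


@pytest.fixture(scope="session")
def solubility_table():
    return load_packaged_table("solubility")


@pytest.fixture(scope="session")
def distribution_table():
    return load_packaged_table("distribution")
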