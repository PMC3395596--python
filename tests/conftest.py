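import numpy as np
import pytest

from alnet.cells import MembraneParams


@pytest.fixture(scope="session")
def pn_params():
    return MembraneParams.default("PN")


@pytest.fixture(scope="session")
def ln_params():
    return MembraneParams.default("LN")


@pytest.fixture(scope="session")
def eln_params():
    return MembraneParams.default("eLN")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
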