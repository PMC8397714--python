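import numpy as np
import pytest

from edmol.chem_core import encode_ecfp
from edmol.decoder import TrainConfig, train_decoder
from edmol.fixtures import FixtureConfig, generate_library

#: library seed shared by the whole suite; all fixture-scale statements in
#: the tests refer to this library
LIBRARY_SEED = 7


@pytest.fixture(scope="session")
def fixture_library():
    return generate_library(FixtureConfig(n_molecules=500, rng_seed=LIBRARY_SEED))


@pytest.fixture(scope="session")
def fixture_pairs(fixture_library):
    return [(encode_ecfp(m), m) for m in fixture_library]


@pytest.fixture(scope="session")
def trained_decoder(fixture_pairs):
    """Desk-scale conditional decoder trained once for the whole session."""
    return train_decoder(fixture_pairs, TrainConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
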