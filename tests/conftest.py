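import numpy as np
import pytest

import barriermc as bm

TABLE1_FRACTIONS = {
    "H": 0.0056, "O": 0.4983, "Na": 0.0171, "Mg": 0.0024, "Al": 0.0456,
    "Si": 0.3158, "S": 0.0012, "K": 0.0192, "Ca": 0.0826, "Fe": 0.0122,
}


@pytest.fixture(scope="session")
def concrete():
    return bm.standard_concrete()


@pytest.fixture(scope="session")
def air():
    return bm.dry_air()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
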