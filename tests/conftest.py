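import numpy as np
import pytest

from boolrepair import fixtures, load_fixture
from boolrepair.rbn import RBNSpec, generate_rbn


@pytest.fixture(scope="session")
def aba():
    return load_fixture("aba_reduced")


@pytest.fixture(scope="session")
def tlgl():
    return load_fixture("tlgl_reduced")


@pytest.fixture
def random_net():
    """Factory for small seeded random networks."""

    def make(n=8, k=2, seed=0, p=0.5):
        return generate_rbn(RBNSpec(n, k, p), np.random.default_rng(seed))

    return make
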