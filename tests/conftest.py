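import numpy as np
import pytest

from splicegain import make_mga_fixture
from splicegain.synth import default_mga_series, simulate_junction_counts


@pytest.fixture(scope="session")
def mga():
    """The packaged Mga-like gene fixture (deterministic, seed 0)."""
    return make_mga_fixture(0)


@pytest.fixture(scope="session")
def mga_counts():
    """Stage-resolved junction counts for the fixture event."""
    return simulate_junction_counts(default_mga_series(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
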