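import numpy as np
import pytest

import fuelscape as fs
from fuelscape.experiment import make_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def small_landscape(fixtures):
    return fixtures.landscape_10x10


@pytest.fixture(scope="session")
def micro_pool():
    """Tiny pool for optimizer-level tests."""
    return fs.generate_pool(6, 12, 12, fs.AreaDistribution(5.0, 10.0), base_seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
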