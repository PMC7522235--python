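import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from holopore.io import Marker
from holopore.simulate import default_databases, default_scheme, default_truths


@pytest.fixture(scope="session")
def scheme():
    return default_scheme(0)


@pytest.fixture(scope="session")
def databases():
    dbs, _ = default_databases(0)
    return dbs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
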