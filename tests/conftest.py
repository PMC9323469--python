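import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ccsai import make_fixture

settings.register_profile(
    "ci", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def methane():
    return make_fixture("methane_like")


@pytest.fixture(scope="session")
def ethane():
    return make_fixture("ethane_like")


@pytest.fixture(scope="session")
def methanol():
    return make_fixture("methanol_like")


@pytest.fixture(scope="session")
def toluene():
    return make_fixture("toluene_like")


@pytest.fixture(scope="session")
def cyclopentane():
    return make_fixture("cyclopentyl_like")


@pytest.fixture(scope="session")
def cpi_pair():
    return make_fixture("cpi2_like"), make_fixture("cpi7_like")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
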