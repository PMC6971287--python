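import numpy as np
import pytest

from distopt import get_scenario


@pytest.fixture(scope="session")
def scenario_a():
    return get_scenario("trimodal_separated")


@pytest.fixture(scope="session")
def scenario_a_data(scenario_a):
    return scenario_a.sample()


@pytest.fixture(scope="session")
def scenario_c():
    return get_scenario("central_dominant")


@pytest.fixture(scope="session")
def scenario_c_data(scenario_c):
    return scenario_c.sample()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
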