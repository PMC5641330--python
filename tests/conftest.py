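import numpy as np
import pytest

from pbpkpd import scenarios
from pbpkpd.engine import simulate
from pbpkpd.parameters import bundled_compound, load_physiology


@pytest.fixture(scope="session")
def compound():
    return bundled_compound()


@pytest.fixture(scope="session")
def rat_physiology():
    return load_physiology("rat")


@pytest.fixture(scope="session")
def human_physiology():
    return load_physiology("human")


@pytest.fixture(scope="session")
def rat_model():
    return scenarios.reference_model("rat")


@pytest.fixture(scope="session")
def human_model():
    return scenarios.reference_model("human")


@pytest.fixture(scope="session")
def rat_result_4(rat_model):
    return simulate(rat_model, scenarios.rat_oral_regimen(4.0), grid_dt_h=0.02)


@pytest.fixture(scope="session")
def rat_result_8(rat_model):
    return simulate(rat_model, scenarios.rat_oral_regimen(8.0), grid_dt_h=0.02)


@pytest.fixture(scope="session")
def human_result_30(human_model):
    return simulate(human_model, scenarios.human_single_dose(30.0))
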