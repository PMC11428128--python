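import numpy as np
import pytest

from patchydsa import (
    BondRule,
    InteractionModel,
    SimulationBox,
    ThermoState,
    target_configuration,
)


@pytest.fixture(scope="session")
def box45():
    return SimulationBox.cubic(4.5)


@pytest.fixture(scope="session")
def thermo65():
    return ThermoState(65.0)


@pytest.fixture(scope="session")
def model4():
    return InteractionModel(eps_patch=4.0)


@pytest.fixture(scope="session")
def model4_two_state():
    return InteractionModel(eps_patch=4.0, bond_rule=BondRule.TWO_STATE)


@pytest.fixture()
def target8(model4, box45):
    return target_configuration(8, model4, box45)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
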