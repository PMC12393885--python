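import numpy as np
import pytest

from klinosim.circuit import ParameterRanges, minimal_topology
from klinosim.environment import Environment
from klinosim.fixtures import blank_parameters


@pytest.fixture(scope="session")
def topology():
    return minimal_topology()


@pytest.fixture(scope="session")
def ranges():
    return ParameterRanges.default()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def blank_params():
    return blank_parameters()


@pytest.fixture(scope="session")
def gaussian_env():
    return Environment.gaussian()


MOTOR = ("SMBDL", "SMBVL", "SMBDR", "SMBVR")


@pytest.fixture()
def neutral_motor_z():
    return {n: 0.5 for n in MOTOR}
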