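import pytest

from popguide import (
    SimulationConfig,
    default_params,
    simulate,
)
from popguide.simulator import DEFAULT_INIT


@pytest.fixture(scope="session")
def guider_params():
    return default_params("guider")


@pytest.fixture(scope="session")
def commensal_params():
    return default_params("none")


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def commensal_course(commensal_params, default_config):
    """One 48-h commensal batch on the shipped defaults, shared read-only."""
    return simulate(commensal_params, DEFAULT_INIT, default_config)
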