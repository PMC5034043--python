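import pytest

from alkylbind.demo import RunConfig, run_demo_study
from alkylbind.systems import single_well_system, three_well_system
from alkylbind.thermo import ThermoState


@pytest.fixture(scope="session")
def thermo():
    return ThermoState()


@pytest.fixture(scope="session")
def single_well():
    return single_well_system()


@pytest.fixture(scope="session")
def three_well():
    return three_well_system()


@pytest.fixture(scope="session")
def demo_report():
    """One shared run of the packaged four-site selectivity study."""
    return run_demo_study(RunConfig(seed=1))
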