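import pytest

from linacclear import MachineGeometry
from linacclear.phantoms import scenario_suite


@pytest.fixture(scope="session")
def machine() -> MachineGeometry:
    return MachineGeometry(clearance_radius_mm=400.0, head_length_mm=600.0)


@pytest.fixture(scope="session")
def scenarios():
    return scenario_suite()
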