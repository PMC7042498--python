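import pytest

from shuntsim import (
    BloodProperties,
    CaseDefinition,
    build_case_network,
    reference_patient,
    solve_steady,
)
from shuntsim.units import l_min_to_m3_s


@pytest.fixture
def blood():
    return BloodProperties(density=1060.0, viscosity=0.005)


@pytest.fixture
def patient():
    return reference_patient()


@pytest.fixture
def mid_case():
    """The 4 mm / alpha = 0.15 grid point with its tabulated CO."""
    return CaseDefinition(
        shunt_diameter=0.004, alpha=0.15, cardiac_output=l_min_to_m3_s(2.458)
    )


@pytest.fixture
def mid_solution(patient, mid_case):
    return solve_steady(build_case_network(patient, mid_case))
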