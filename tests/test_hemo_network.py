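import math
from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shuntsim import (
    BloodProperties,
    CaseDefinition,
    OutletBC,
    PatientNetwork,
    ShuntSpec,
    build_case_network,
    reference_patient,
    solve_linear_oracle,
    solve_steady,
)
from shuntsim.errors import (
    InvalidCaseError,
    InvalidSpecError,
    ReversedShuntError,
    SolverError,
)
from shuntsim.hemo_network import (
    MASS_RESIDUAL_LIMIT,
    OUTLET_NAMES,
    PULMONARY_OUTLETS,
    SYSTEMIC_OUTLETS,
)
from shuntsim.units import l_min_to_m3_s


class TestTypeInvariants:
    def test_blood_properties_positive(self):
        with pytest.raises(InvalidSpecError):
            BloodProperties(density=-1.0)
        with pytest.raises(InvalidSpecError):
            BloodProperties(viscosity=0.0)

    def test_outlet_names_restricted(self):
        with pytest.raises(InvalidSpecError):
            OutletBC(name="AAO", resistance=1e8, area=1e-5)

    def test_outlet_positive_fields(self):
        with pytest.raises(InvalidSpecError):
            OutletBC(name="IA", resistance=-1e8, area=1e-5)

    def test_patient_needs_all_six_outlets(self, patient):
        with pytest.raises(InvalidSpecError):
            replace(patient, outlets=patient.outlets[:5])

    def test_patient_asymmetry_positive(self, patient):
        with pytest.raises(InvalidSpecError):
            replace(patient, lpa_rpa_asymmetry=0.0)

    def test_case_alpha_bounds(self):
        with pytest.raises(InvalidCaseError):
            CaseDefinition(shunt_diameter=0.004, alpha=1.0, cardiac_output=1e-5)
        with pytest.raises(InvalidCaseError):
            CaseDefinition(shunt_diameter=0.004, alpha=-0.1, cardiac_output=1e-5)


class TestBuildCaseNetwork:
    def test_atresia_has_no_mpa_inflow(self, patient):
        case = CaseDefinition(shunt_diameter=0.003, alpha=0.0,
                              cardiac_output=l_min_to_m3_s(2.122))
        net = build_case_network(patient, case)
        assert net.mpa_inflow == 0.0
        assert net.n_inlets == 1
        assert net.aortic_inflow == pytest.approx(case.cardiac_output)

    def test_inflow_split_arithmetic(self, patient):
        co = l_min_to_m3_s(2.798)
        case = CaseDefinition(shunt_diameter=0.005, alpha=0.30, cardiac_output=co)
        net = build_case_network(patient, case)
        # alpha*CO = 0.30 * 2.798 = 0.8394 L/min
        assert net.mpa_inflow == pytest.approx(l_min_to_m3_s(0.8394), rel=1e-12)
        assert net.aortic_inflow + net.mpa_inflow == pytest.approx(co, rel=1e-14)

    def test_topology_counts(self, patient, mid_case):
        net = build_case_network(patient, mid_case)
        assert net.n_inlets == 2
        assert net.n_outlets == 6
        assert net.shunt.diameter == pytest.approx(0.004)

    def test_shunt_diameter_taken_from_case(self, patient):
        case = CaseDefinition(shunt_diameter=0.0035, alpha=0.1,
                              cardiac_output=l_min_to_m3_s(2.303))
        net = build_case_network(patient, case)
        assert net.shunt.diameter == pytest.approx(0.0035)


def _single_outlet_patient(resistance, blood):
    """Degenerate network: shunt feeds a pulmonary side whose resistances are
    enormous, so effectively one systemic outlet carries the flow."""
    big = 1e20
    outlets = tuple(
        OutletBC(name=n, resistance=resistance if n == "IA" else big, area=1e-5)
        for n in OUTLET_NAMES
    )
    return PatientNetwork(
        blood=blood, outlets=outlets,
        shunt=ShuntSpec(diameter=0.004, minor_loss_coefficient=0.0),
    )


class TestSolveSteady:
    def test_single_outlet_closed_form(self, blood):
        # Node pressure = R*Q + reference for a lone linear outlet.
        r, q = 5.0e8, 2.0e-5
        patient = _single_outlet_patient(r, blood)
        case = CaseDefinition(shunt_diameter=0.004, alpha=0.0, cardiac_output=q)
        sol = solve_steady(build_case_network(patient, case))
        assert sol.aortic_pressure == pytest.approx(r * q, rel=1e-6)

    def test_reference_pressure_offsets_node(self, blood):
        r, q, pref = 5.0e8, 2.0e-5, 500.0
        patient = replace(_single_outlet_patient(r, blood), reference_pressure=pref)
        case = CaseDefinition(shunt_diameter=0.004, alpha=0.0, cardiac_output=q)
        sol = solve_steady(build_case_network(patient, case))
        assert sol.aortic_pressure == pytest.approx(r * q + pref, rel=1e-6)

    def test_symmetric_network_equal_pulmonary_flows(self, patient, mid_case):
        sol = solve_steady(build_case_network(patient, mid_case))
        assert sol.outlet_flow("LPA") == pytest.approx(
            sol.outlet_flow("RPA"), rel=1e-12
        )

    def test_asymmetry_shifts_split(self, patient, mid_case):
        asym = replace(patient, lpa_rpa_asymmetry=1.5)
        sol = solve_steady(build_case_network(asym, mid_case))
        assert sol.outlet_flow("LPA") < sol.outlet_flow("RPA")
        assert sol.outlet_flow("LPA") == pytest.approx(
            sol.outlet_flow("RPA") / 1.5, rel=1e-10
        )

    @pytest.mark.parametrize("alpha", [0.0, 0.15, 0.30])
    @pytest.mark.parametrize("d_mm", [3.0, 4.0, 5.0])
    def test_mass_conservation(self, patient, d_mm, alpha):
        case = CaseDefinition(shunt_diameter=d_mm * 1e-3, alpha=alpha,
                              cardiac_output=l_min_to_m3_s(2.458))
        sol = solve_steady(build_case_network(patient, case))
        assert sol.converged
        assert sol.residual <= MASS_RESIDUAL_LIMIT

    def test_linear_oracle_equivalence(self, patient, blood):
        # With K = 0 the Newton path must agree with direct 2x2 nodal
        # analysis to 1e-10 relative.
        lin = replace(patient, shunt=replace(patient.shunt,
                                             minor_loss_coefficient=0.0))
        case = CaseDefinition(shunt_diameter=0.004, alpha=0.2,
                              cardiac_output=l_min_to_m3_s(2.458))
        net = build_case_network(lin, case)
        sol = solve_steady(net)
        pa, pp = solve_linear_oracle(net, blood)
        assert sol.aortic_pressure == pytest.approx(pa, rel=1e-10)
        assert sol.pulmonary_pressure == pytest.approx(pp, rel=1e-10)

    def test_all_outlet_flows_nonnegative(self, mid_solution):
        for name in OUTLET_NAMES:
            assert mid_solution.outlet_flow(name) >= 0

    def test_shunt_flow_aorta_to_pa(self, mid_solution):
        assert mid_solution.element_flows["shunt"] >= 0
        assert mid_solution.aortic_pressure > mid_solution.pulmonary_pressure

    def test_reversed_shunt_flagged(self, blood):
        # Pulmonary outlets far stiffer than systemic + large prescribed MPA
        # inflow force the pulmonary node above the aortic node.
        outlets = tuple(
            OutletBC(name=n, resistance=1e8 if n in SYSTEMIC_OUTLETS else 1e12,
                     area=1e-5)
            for n in OUTLET_NAMES
        )
        patient = PatientNetwork(blood=blood, outlets=outlets,
                                 shunt=ShuntSpec(diameter=0.004))
        case = CaseDefinition(shunt_diameter=0.004, alpha=0.5,
                              cardiac_output=l_min_to_m3_s(2.5))
        with pytest.raises(ReversedShuntError):
            solve_steady(build_case_network(patient, case))

    def test_nonconvergence_carries_residual(self, patient, mid_case):
        net = build_case_network(patient, mid_case)
        with pytest.raises(SolverError) as excinfo:
            solve_steady(net, max_iter=0, tol=1e-30)
        assert excinfo.value.residual > 0

    @settings(max_examples=25, deadline=None)
    @given(
        alpha=st.floats(min_value=0.0, max_value=0.3),
        d_mm=st.floats(min_value=3.0, max_value=5.0),
        k=st.floats(min_value=0.0, max_value=5.0),
    )
    def test_mass_conservation_property(self, alpha, d_mm, k):
        patient = reference_patient()
        patient = replace(
            patient, shunt=replace(patient.shunt, minor_loss_coefficient=k)
        )
        case = CaseDefinition(shunt_diameter=d_mm * 1e-3, alpha=alpha,
                              cardiac_output=l_min_to_m3_s(2.458))
        sol = solve_steady(build_case_network(patient, case))
        assert sol.residual <= MASS_RESIDUAL_LIMIT


class TestMonotonicity:
    def _qp(self, patient, d_mm, alpha, co_l_min=2.458):
        case = CaseDefinition(shunt_diameter=d_mm * 1e-3, alpha=alpha,
                              cardiac_output=l_min_to_m3_s(co_l_min))
        sol = solve_steady(build_case_network(patient, case))
        return sum(sol.outlet_flow(n) for n in PULMONARY_OUTLETS)

    def test_qp_nondecreasing_in_diameter(self, patient):
        qps = [self._qp(patient, d, 0.15) for d in (3.0, 3.5, 4.0, 4.5, 5.0)]
        assert all(b >= a for a, b in zip(qps, qps[1:]))

    def test_qp_nondecreasing_in_alpha(self, patient):
        qps = [self._qp(patient, 4.0, a) for a in (0.0, 0.1, 0.2, 0.3)]
        assert all(b >= a for a, b in zip(qps, qps[1:]))


def test_solution_json_round_trip(tmp_path, mid_solution):
    import json

    path = tmp_path / "solution.json"
    mid_solution.to_json(path)
    data = json.loads(path.read_text())
    assert data["converged"] is True
    assert data["aortic_pressure_Pa"] == pytest.approx(
        mid_solution.aortic_pressure
    )
    assert set(data["element_flows_m3_s"]) == {"shunt", *OUTLET_NAMES}
    assert math.isclose(
        data["port_states"]["out:LPA"]["flow_m3_s"],
        mid_solution.outlet_flow("LPA"),
    )
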