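"""Evaluation metrics computed from a converged flow solution.

Power loss is the total-energy flux balance over the domain ports,

    PL = sum_in (p + 1/2 rho v^2) Q  -  sum_out (p + 1/2 rho v^2) Q,

reported in mW; relative power loss divides by the inlet energy flux
(the flux includes the factor Q — without it the ratio is not
dimensionless).  An independent route to the same number sums the
per-element total-pressure dissipations dP * Q over the shunt and the six
outlet resistors; the two agree to round-off on any converged solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import (
    IncompleteSolutionError,
    InvalidArgumentError,
    UndefinedRatioError,
)
from .hemo_network import (
    PULMONARY_OUTLETS,
    SYSTEMIC_OUTLETS,
    FlowSolution,
)
from .oxygen_transport import OxygenReport
from .units import W_TO_MW


@dataclass(frozen=True)
class CaseReport:
    """All evaluation metrics for one (diameter, alpha) grid case.

    Power loss in mW, relative power loss in percent, flows inside the
    ``oxygen`` report in mL/min.  ``status`` is ``"ok"`` for a feasible
    case; infeasible oxygen regimes or solver failures are recorded, not
    dropped (``oxygen`` is then None).
    """

    diameter_mm: float
    alpha: float
    qp_qs: float
    q_lpa_rpa: float
    power_loss_mw: float
    relative_power_loss_pct: float
    reynolds_shunt: float
    oxygen: OxygenReport | None = None
    mass_residual_kg_s: float = 0.0
    iterations: int = 0
    status: str = "ok"
    detail: str = field(default="", compare=False)


def stenosis_ratio(mpa_flow: float, cardiac_output: float) -> float:
    """Stenosis ratio alpha = Q_MPA / CO (0 = atresia)."""
    if cardiac_output <= 0:
        raise InvalidArgumentError(
            f"cardiac_output must be > 0, got {cardiac_output}"
        )
    if mpa_flow < 0:
        raise InvalidArgumentError(f"mpa_flow must be >= 0, got {mpa_flow}")
    if mpa_flow > cardiac_output:
        raise InvalidArgumentError(
            f"mpa_flow {mpa_flow} exceeds cardiac output {cardiac_output}"
        )
    return mpa_flow / cardiac_output


def flow_splits(solution: FlowSolution) -> tuple[float, float]:
    """(Qp/Qs, Q_LPA/Q_RPA) from the six outlet flows of a solution."""
    q_lpa = solution.outlet_flow("LPA")
    q_rpa = solution.outlet_flow("RPA")
    if q_rpa == 0:
        raise UndefinedRatioError("RPA flow is zero; LPA/RPA split undefined")
    q_pulmonary = sum(solution.outlet_flow(n) for n in PULMONARY_OUTLETS)
    q_systemic = sum(solution.outlet_flow(n) for n in SYSTEMIC_OUTLETS)
    if q_systemic == 0:
        raise UndefinedRatioError("systemic flow is zero; Qp/Qs undefined")
    return q_pulmonary / q_systemic, q_lpa / q_rpa


def _energy_flux(port, rho: float) -> float:
    """Total-energy flux (p + 1/2 rho v^2) Q through one port, W."""
    return (port.pressure + 0.5 * rho * port.velocity**2) * port.flow


def power_loss(solution: FlowSolution) -> float:
    """Power loss over the domain ports, in mW."""
    rho = solution.blood.density
    inlets = solution.inlet_ports
    outlets = solution.outlet_ports
    if not inlets or not outlets:
        raise IncompleteSolutionError("solution is missing inlet or outlet ports")
    flux_in = sum(_energy_flux(p, rho) for p in inlets.values())
    flux_out = sum(_energy_flux(p, rho) for p in outlets.values())
    return (flux_in - flux_out) * W_TO_MW


def inlet_energy_flux(solution: FlowSolution) -> float:
    """Total inlet energy flux sum_in (p + 1/2 rho v^2) Q, in W."""
    rho = solution.blood.density
    inlets = solution.inlet_ports
    if not inlets:
        raise IncompleteSolutionError("solution has no inlet ports")
    return sum(_energy_flux(p, rho) for p in inlets.values())


def relative_power_loss(solution: FlowSolution) -> float:
    """Power loss as a percentage of the inlet energy flux."""
    flux_in = inlet_energy_flux(solution)
    if flux_in <= 0:
        raise UndefinedRatioError(
            f"inlet energy flux {flux_in} W is not positive; RPL undefined"
        )
    return power_loss(solution) / W_TO_MW / flux_in * 100.0


def element_dissipation(solution: FlowSolution, network) -> float:
    """Independent oracle for the port-based power loss, in mW.

    Sums total-pressure drop times flow over every dissipative element:
    the shunt (static drop between nodes) and the six outlet resistors
    (node total pressure down to the outlet port total pressure).  Inlet
    entry is lossless by construction.
    """
    rho = solution.blood.density
    pa = solution.aortic_pressure
    pp = solution.pulmonary_pressure
    total = (pa - pp) * solution.element_flows["shunt"]
    for name in SYSTEMIC_OUTLETS + PULMONARY_OUTLETS:
        port = solution.port_states[f"out:{name}"]
        node_p = pa if name in SYSTEMIC_OUTLETS else pp
        total_out = port.pressure + 0.5 * rho * port.velocity**2
        total += (node_p - total_out) * port.flow
    return total * W_TO_MW
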