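"""Lumped-parameter (0D) circulation topology and steady-state solver.

The arterial tree is collapsed to two pressure nodes:

* an **aortic node** fed by the ascending-aorta inflow ``(1 - alpha) * CO``
  and drained by four systemic outlet resistors (IA, LCA, LSA, DAO);
* a **pulmonary node** fed by the main-pulmonary-artery inflow
  ``alpha * CO`` and drained by two pulmonary outlet resistors (LPA, RPA).

A single nonlinear shunt element (Poiseuille term plus minor-loss term)
bridges the aortic node to the pulmonary node.  All outlets discharge to a
common reference pressure (default 0 Pa).  Steady state is found by damped
Newton iteration on the two node pressures; the linearized network provides
both the initial guess and an independent closed-form oracle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import shunt_hydraulics
from .errors import (
    IncompleteSolutionError,
    InvalidArgumentError,
    InvalidCaseError,
    InvalidSpecError,
    ReversedShuntError,
    SolverError,
)

SYSTEMIC_OUTLETS = ("IA", "LCA", "LSA", "DAO")
PULMONARY_OUTLETS = ("LPA", "RPA")
OUTLET_NAMES = SYSTEMIC_OUTLETS + PULMONARY_OUTLETS

#: Mass-balance contract on converged solutions (kg/s).
MASS_RESIDUAL_LIMIT = 1.0e-8
#: Newton convergence tolerance on nodal flow imbalance (m^3/s); far
#: stricter than the kg/s contract so that downstream energy bookkeeping
#: (port flux vs per-element dissipation) agrees to <= 1e-8 relative.
FLOW_RESIDUAL_TOL = 1.0e-14
MAX_NEWTON_ITER = 100


@dataclass(frozen=True)
class BloodProperties:
    """Newtonian blood model: density (kg/m^3) and dynamic viscosity (Pa.s)."""

    density: float = 1060.0
    viscosity: float = 0.005

    def __post_init__(self):
        if self.density <= 0:
            raise InvalidSpecError(f"density must be > 0, got {self.density}")
        if self.viscosity <= 0:
            raise InvalidSpecError(f"viscosity must be > 0, got {self.viscosity}")


@dataclass(frozen=True)
class OutletBC:
    """One outlet boundary: lumped resistance plus porous-zone geometry.

    ``resistance`` is stored in SI (Pa.s/m^3); published values in
    MPa.s.m^-3 are converted at the I/O boundary.
    """

    name: str
    resistance: float
    area: float
    porous_length: float = 0.01

    def __post_init__(self):
        if self.name not in OUTLET_NAMES:
            raise InvalidSpecError(
                f"outlet name must be one of {OUTLET_NAMES}, got {self.name!r}"
            )
        for attr in ("resistance", "area", "porous_length"):
            if getattr(self, attr) <= 0:
                raise InvalidSpecError(
                    f"{self.name}: {attr} must be > 0, got {getattr(self, attr)}"
                )


@dataclass(frozen=True)
class ShuntSpec:
    """Central shunt tube: inner diameter, length and minor-loss coefficient."""

    diameter: float
    length: float = 0.02
    minor_loss_coefficient: float = 1.5

    def __post_init__(self):
        if self.diameter <= 0:
            raise InvalidSpecError(f"diameter must be > 0, got {self.diameter}")
        if self.length <= 0:
            raise InvalidSpecError(f"length must be > 0, got {self.length}")
        if self.minor_loss_coefficient < 0:
            raise InvalidSpecError(
                f"minor-loss K must be >= 0, got {self.minor_loss_coefficient}"
            )

    @property
    def area(self) -> float:
        return math.pi * self.diameter**2 / 4.0


@dataclass(frozen=True)
class PatientNetwork:
    """Complete parameter set for one virtual patient.

    ``lpa_rpa_asymmetry`` multiplies the LPA series resistance to stand in
    for the 3D branching geometry; 1.0 gives a perfectly symmetric split.
    """

    blood: BloodProperties
    outlets: tuple[OutletBC, ...]
    shunt: ShuntSpec
    lpa_rpa_asymmetry: float = 1.0
    aortic_root_area: float = 1.131e-4
    mpa_area: float = 5.027e-5
    reference_pressure: float = 0.0

    def __post_init__(self):
        names = [o.name for o in self.outlets]
        if sorted(names) != sorted(OUTLET_NAMES):
            raise InvalidSpecError(
                f"need exactly the six outlets {OUTLET_NAMES}, got {names}"
            )
        if self.lpa_rpa_asymmetry <= 0:
            raise InvalidSpecError(
                f"lpa_rpa_asymmetry must be > 0, got {self.lpa_rpa_asymmetry}"
            )
        if self.aortic_root_area <= 0 or self.mpa_area <= 0:
            raise InvalidSpecError("inlet areas must be > 0")

    def outlet(self, name: str) -> OutletBC:
        for o in self.outlets:
            if o.name == name:
                return o
        raise KeyError(name)

    def effective_resistance(self, name: str) -> float:
        """Outlet resistance including the LPA asymmetry multiplier (Pa.s/m^3)."""
        r = self.outlet(name).resistance
        if name == "LPA":
            r *= self.lpa_rpa_asymmetry
        return r

    def with_shunt(self, shunt: ShuntSpec) -> "PatientNetwork":
        return replace(self, shunt=shunt)


@dataclass(frozen=True)
class CaseDefinition:
    """One grid point: shunt diameter (m), stenosis ratio alpha, CO (m^3/s)."""

    shunt_diameter: float
    alpha: float
    cardiac_output: float

    def __post_init__(self):
        if not 0.0 <= self.alpha < 1.0:
            raise InvalidCaseError(f"alpha must lie in [0, 1), got {self.alpha}")
        if self.cardiac_output <= 0:
            raise InvalidCaseError(
                f"cardiac_output must be > 0, got {self.cardiac_output}"
            )
        if self.shunt_diameter <= 0:
            raise InvalidCaseError(
                f"shunt_diameter must be > 0, got {self.shunt_diameter}"
            )


@dataclass(frozen=True)
class PortState:
    """Static pressure (Pa), mean velocity (m/s) and flow (m^3/s) at a port."""

    pressure: float
    velocity: float
    flow: float


@dataclass(frozen=True)
class CaseNetwork:
    """Assembled two-node network for one case, ready for the solver."""

    patient: PatientNetwork
    case: CaseDefinition
    aortic_inflow: float
    mpa_inflow: float

    @property
    def shunt(self) -> ShuntSpec:
        return self.patient.shunt

    @property
    def n_inlets(self) -> int:
        return 2 if self.mpa_inflow > 0 else 1

    @property
    def n_outlets(self) -> int:
        return len(self.patient.outlets)


@dataclass(frozen=True)
class FlowSolution:
    """Converged node pressures, element flows and per-port states."""

    aortic_pressure: float
    pulmonary_pressure: float
    element_flows: dict[str, float]
    port_states: dict[str, PortState]
    converged: bool
    residual: float  # kg/s
    iterations: int = 0
    blood: BloodProperties = field(default_factory=BloodProperties)
    reference_pressure: float = 0.0

    @property
    def inlet_ports(self) -> dict[str, PortState]:
        return {k: v for k, v in self.port_states.items() if k.startswith("in:")}

    @property
    def outlet_ports(self) -> dict[str, PortState]:
        return {k: v for k, v in self.port_states.items() if k.startswith("out:")}

    def outlet_flow(self, name: str) -> float:
        try:
            return self.port_states[f"out:{name}"].flow
        except KeyError as exc:
            raise IncompleteSolutionError(f"missing outlet port {name!r}") from exc

    def to_json(self, path=None) -> str:
        """Serialize node pressures, flows and convergence record to JSON."""
        payload = {
            "aortic_pressure_Pa": self.aortic_pressure,
            "pulmonary_pressure_Pa": self.pulmonary_pressure,
            "element_flows_m3_s": dict(self.element_flows),
            "port_states": {
                k: {"pressure_Pa": p.pressure, "velocity_m_s": p.velocity,
                    "flow_m3_s": p.flow}
                for k, p in self.port_states.items()
            },
            "converged": self.converged,
            "residual_kg_s": self.residual,
            "iterations": self.iterations,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def build_case_network(patient: PatientNetwork, case: CaseDefinition) -> CaseNetwork:
    """Assemble the two-node network for one (diameter, alpha, CO) case.

    The total cardiac output is split so that the aortic inflow carries
    ``(1 - alpha) * CO`` and the MPA inflow carries ``alpha * CO``; with
    alpha = 0 (atresia) the MPA inlet disappears and all pulmonary flow
    must arrive through the shunt.
    """
    if not 0.0 <= case.alpha < 1.0:
        raise InvalidCaseError(f"alpha must lie in [0, 1), got {case.alpha}")
    shunt = patient.shunt
    if not math.isclose(shunt.diameter, case.shunt_diameter, rel_tol=1e-12):
        shunt = replace(shunt, diameter=case.shunt_diameter)
    pat = patient.with_shunt(shunt)
    co = case.cardiac_output
    return CaseNetwork(
        patient=pat,
        case=case,
        aortic_inflow=(1.0 - case.alpha) * co,
        mpa_inflow=case.alpha * co,
    )


def _linearized_pressures(network: CaseNetwork, blood: BloodProperties,
                          shunt_conductance: float | None = None):
    """Closed-form nodal solution with the shunt replaced by a linear
    conductance (its Poiseuille term by default).  Used as the Newton
    initial guess and as the K = 0 oracle.

    Returns (p_aortic, p_pulmonary) as gauge pressures above reference.
    """
    pat = network.patient
    g_sys = sum(1.0 / pat.effective_resistance(n) for n in SYSTEMIC_OUTLETS)
    g_pul = sum(1.0 / pat.effective_resistance(n) for n in PULMONARY_OUTLETS)
    if shunt_conductance is None:
        r_pois = shunt_hydraulics.poiseuille_resistance(network.shunt, blood)
        shunt_conductance = 1.0 / r_pois
    g_sh = shunt_conductance
    # [g_sys + g_sh, -g_sh; -g_sh, g_pul + g_sh] [pa, pp] = [q_aao, q_mpa]
    a = np.array([[g_sys + g_sh, -g_sh], [-g_sh, g_pul + g_sh]])
    b = np.array([network.aortic_inflow, network.mpa_inflow])
    pa, pp = np.linalg.solve(a, b)
    return float(pa), float(pp)


def solve_linear_oracle(network: CaseNetwork, blood: BloodProperties):
    """Direct 2x2 nodal analysis valid when the shunt minor-loss K is 0.

    Kept deliberately separate from the Newton path so the two can be
    compared as independent routes to the same answer.
    """
    pa, pp = _linearized_pressures(network, blood)
    return pa + network.patient.reference_pressure, pp + network.patient.reference_pressure


def _assemble_solution(network: CaseNetwork, blood: BloodProperties,
                       pa: float, pp: float, iterations: int) -> FlowSolution:
    """Build port states and the mass-balance record from node pressures."""
    pat = network.patient
    pref = pat.reference_pressure
    rho = blood.density
    dp_shunt = pa - pp
    q_shunt = shunt_hydraulics.shunt_flow(network.shunt, dp_shunt, blood)

    element_flows: dict[str, float] = {"shunt": q_shunt}
    port_states: dict[str, PortState] = {}

    # Inlet ports: lossless entry into the node, so the port's total
    # pressure equals the node static pressure (node KE treated as 0).
    q_aao = network.aortic_inflow
    v_aao = q_aao / pat.aortic_root_area
    port_states["in:AAO"] = PortState(
        pressure=pa + pref - 0.5 * rho * v_aao**2, velocity=v_aao, flow=q_aao
    )
    if network.mpa_inflow > 0:
        q_mpa = network.mpa_inflow
        v_mpa = q_mpa / pat.mpa_area
        port_states["in:MPA"] = PortState(
            pressure=pp + pref - 0.5 * rho * v_mpa**2, velocity=v_mpa, flow=q_mpa
        )

    total_out = 0.0
    for name in OUTLET_NAMES:
        node_p = pa if name in SYSTEMIC_OUTLETS else pp
        q = node_p / pat.effective_resistance(name)
        element_flows[name] = q
        v = q / pat.outlet(name).area
        port_states[f"out:{name}"] = PortState(pressure=pref, velocity=v, flow=q)
        total_out += q

    total_in = q_aao + network.mpa_inflow
    residual_kg_s = rho * abs(total_in - total_out)
    return FlowSolution(
        aortic_pressure=pa + pref,
        pulmonary_pressure=pp + pref,
        element_flows=element_flows,
        port_states=port_states,
        converged=True,
        residual=residual_kg_s,
        iterations=iterations,
        blood=blood,
        reference_pressure=pref,
    )


def solve_steady(network: CaseNetwork, blood: BloodProperties | None = None,
                 tol: float = FLOW_RESIDUAL_TOL,
                 max_iter: int = MAX_NEWTON_ITER) -> FlowSolution:
    """Solve the two-node steady-flow balance by damped Newton iteration.

    Unknowns are the gauge pressures at the aortic and pulmonary nodes.
    Residuals are the nodal flow imbalances (m^3/s); convergence requires
    both below ``tol``.  The linearized network supplies the initial guess.

    Raises
    ------
    SolverError
        If the residual has not dropped below ``tol`` after ``max_iter``
        iterations (carries the last residual).
    ReversedShuntError
        If the converged shunt flow is directed pulmonary-to-aortic.
    """
    if blood is None:
        blood = network.patient.blood
    pat = network.patient
    for name in OUTLET_NAMES:
        if pat.effective_resistance(name) <= 0:
            raise InvalidArgumentError(f"outlet {name} has nonpositive resistance")

    g_sys = sum(1.0 / pat.effective_resistance(n) for n in SYSTEMIC_OUTLETS)
    g_pul = sum(1.0 / pat.effective_resistance(n) for n in PULMONARY_OUTLETS)

    pa, pp = _linearized_pressures(network, blood)
    x = np.array([pa, pp])

    def residual(xv):
        pa_, pp_ = xv
        q_sh = shunt_hydraulics.shunt_flow(network.shunt, pa_ - pp_, blood)
        f1 = network.aortic_inflow - g_sys * pa_ - q_sh
        f2 = network.mpa_inflow + q_sh - g_pul * pp_
        return np.array([f1, f2]), q_sh

    f, _ = residual(x)
    it = 0
    while np.max(np.abs(f)) > tol and it < max_iter:
        dq_ddp = shunt_hydraulics.shunt_flow_derivative(
            network.shunt, x[0] - x[1], blood
        )
        jac = np.array(
            [[-g_sys - dq_ddp, dq_ddp], [dq_ddp, -g_pul - dq_ddp]]
        )
        step = np.linalg.solve(jac, -f)
        # Damped update: halve the step until the residual norm decreases.
        lam = 1.0
        f_norm = np.max(np.abs(f))
        for _ in range(30):
            f_new, _ = residual(x + lam * step)
            if np.max(np.abs(f_new)) < f_norm:
                break
            lam *= 0.5
        x = x + lam * step
        f, _ = residual(x)
        it += 1

    if np.max(np.abs(f)) > tol:
        raise SolverError(
            f"Newton failed to converge after {max_iter} iterations "
            f"(flow residual {np.max(np.abs(f)):.3e} m^3/s)",
            residual=float(np.max(np.abs(f))),
        )

    q_sh = shunt_hydraulics.shunt_flow(network.shunt, x[0] - x[1], blood)
    if q_sh < -tol:
        raise ReversedShuntError(
            f"converged shunt flow is pulmonary-to-aortic ({q_sh:.3e} m^3/s)"
        )
    return _assemble_solution(network, blood, float(x[0]), float(x[1]), it)
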