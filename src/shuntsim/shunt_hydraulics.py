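"""Constitutive laws for the shunt tube and porous outlet zones.

The shunt pressure drop combines a Poiseuille (laminar, linear) term with a
dimensionless minor-loss term for the anastomoses:

    dP = (128 mu L / (pi d^4)) Q  +  K (rho/2) (Q/A)^2 sign(Q)

which is odd and strictly increasing in Q for any K >= 0, so its inverse
(flow from pressure drop) is single-valued.  The porous-zone conversion
turns a lumped outlet resistance R into the per-area viscous coefficient
X = R A / (mu l).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

from .errors import InvalidArgumentError, InvalidSpecError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .hemo_network import BloodProperties, ShuntSpec


@dataclass(frozen=True)
class ShuntFlowState:
    """Diagnostic state of the shunt element at a converged operating point."""

    flow: float            # m^3/s
    mean_velocity: float   # m/s
    pressure_drop: float   # Pa
    reynolds: float        # dimensionless


def poiseuille_resistance(spec: "ShuntSpec", blood: "BloodProperties") -> float:
    """Linear (Poiseuille) resistance of the shunt tube, Pa.s/m^3."""
    if spec.diameter <= 0:
        raise InvalidSpecError(f"diameter must be > 0, got {spec.diameter}")
    return 128.0 * blood.viscosity * spec.length / (math.pi * spec.diameter**4)


def _quadratic_coefficient(spec: "ShuntSpec", blood: "BloodProperties") -> float:
    area = math.pi * spec.diameter**2 / 4.0
    return spec.minor_loss_coefficient * blood.density / (2.0 * area**2)


def shunt_pressure_drop(spec: "ShuntSpec", flow: float,
                        blood: "BloodProperties") -> float:
    """Static pressure drop across the shunt at volumetric flow ``flow``.

    Odd and strictly increasing in ``flow``; zero at zero flow.
    """
    if spec.diameter <= 0:
        raise InvalidSpecError(f"diameter must be > 0, got {spec.diameter}")
    lin = poiseuille_resistance(spec, blood) * flow
    quad = _quadratic_coefficient(spec, blood) * flow * abs(flow)
    return lin + quad


def shunt_flow(spec: "ShuntSpec", pressure_drop: float,
               blood: "BloodProperties") -> float:
    """Invert the shunt law: flow producing the given pressure drop.

    Closed form: for dp >= 0 solve a Q^2 + b Q = dp with
    a = K rho / (2 A^2), b = 128 mu L / (pi d^4); odd extension for dp < 0.
    """
    b = poiseuille_resistance(spec, blood)
    a = _quadratic_coefficient(spec, blood)
    dp = abs(pressure_drop)
    # cancellation-free root: 2 dp / (b + sqrt(b^2 + 4 a dp)), exact dp/b
    # in the a -> 0 limit
    q = 2.0 * dp / (b + math.sqrt(b * b + 4.0 * a * dp))
    return math.copysign(q, pressure_drop) if pressure_drop != 0 else 0.0


def shunt_flow_derivative(spec: "ShuntSpec", pressure_drop: float,
                          blood: "BloodProperties") -> float:
    """d(flow)/d(pressure_drop) of the inverted shunt law (for Newton)."""
    b = poiseuille_resistance(spec, blood)
    a = _quadratic_coefficient(spec, blood)
    if a == 0.0:
        return 1.0 / b
    return 1.0 / math.sqrt(b * b + 4.0 * a * abs(pressure_drop))


def reynolds_number(flow: float, diameter: float,
                    blood: "BloodProperties") -> float:
    """Tube Reynolds number Re = rho v d / mu with v = Q / (pi d^2 / 4)."""
    if diameter <= 0:
        raise InvalidArgumentError(f"diameter must be > 0, got {diameter}")
    area = math.pi * diameter**2 / 4.0
    velocity = abs(flow) / area
    return blood.density * velocity * diameter / blood.viscosity


def shunt_state(spec: "ShuntSpec", flow: float,
                blood: "BloodProperties") -> ShuntFlowState:
    """Full diagnostic triple (v, dP, Re) at a given shunt flow."""
    area = math.pi * spec.diameter**2 / 4.0
    return ShuntFlowState(
        flow=flow,
        mean_velocity=flow / area,
        pressure_drop=shunt_pressure_drop(spec, flow, blood),
        reynolds=reynolds_number(flow, spec.diameter, blood),
    )


def viscous_resistance(resistance_mpa_s_m3: float, area: float,
                       viscosity: float, length: float) -> float:
    """Convert a lumped outlet resistance to the porous viscous coefficient.

    X = R A / (mu l), with R given in MPa.s.m^-3 (the published unit) and
    converted to Pa.s/m^3 internally; the result X is in m^-2.
    """
    for label, value in (
        ("resistance", resistance_mpa_s_m3),
        ("area", area),
        ("viscosity", viscosity),
        ("length", length),
    ):
        if value <= 0:
            raise InvalidArgumentError(f"{label} must be > 0, got {value}")
    r_si = resistance_mpa_s_m3 * 1.0e6
    return r_si * area / (viscosity * length)


def resistance_from_viscous(x: float, area: float, viscosity: float,
                            length: float) -> float:
    """Inverse of :func:`viscous_resistance`: recover R in MPa.s.m^-3."""
    for label, value in (
        ("viscous coefficient", x),
        ("area", area),
        ("viscosity", viscosity),
        ("length", length),
    ):
        if value <= 0:
            raise InvalidArgumentError(f"{label} must be > 0, got {value}")
    return x * viscosity * length / area * 1.0e-6
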