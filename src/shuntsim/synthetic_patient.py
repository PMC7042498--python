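"""Virtual-patient generation.

:func:`reference_patient` returns the deterministic network built from the
published constants (six outlet resistances, blood density/viscosity,
symmetric pulmonary split).  :func:`generate_patient` perturbs it: outlet
resistances drawn log-normally around the reference with a configurable
coefficient of variation, lumen areas / pulmonary asymmetry / shunt
minor-loss coefficient drawn uniformly in configurable ranges.  Same seed,
same patient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .hemo_network import (
    OUTLET_NAMES,
    BloodProperties,
    OutletBC,
    PatientNetwork,
    ShuntSpec,
)
from .units import MPA_S_M3_TO_PA_S_M3

#: Published outlet resistances, MPa.s.m^-3 (IA, LCA, LSA, DAO, LPA, RPA).
REFERENCE_RESISTANCES_MPA = {
    "IA": 2383.0,
    "LCA": 4792.0,
    "LSA": 4260.0,
    "DAO": 1152.0,
    "LPA": 131.0,
    "RPA": 131.0,
}

REFERENCE_DENSITY = 1060.0    # kg/m^3
REFERENCE_VISCOSITY = 0.005   # Pa.s


def _circle_area(diameter_m: float) -> float:
    return math.pi * diameter_m**2 / 4.0


#: Default lumen areas (m^2) from pediatric-scale vessel diameters; the
#: source geometry prints none, so these are config-exposed estimates.
REFERENCE_AREAS = {
    "IA": _circle_area(0.006),
    "LCA": _circle_area(0.004),
    "LSA": _circle_area(0.004),
    "DAO": _circle_area(0.009),
    "LPA": _circle_area(0.005),
    "RPA": _circle_area(0.005),
}

REFERENCE_POROUS_LENGTH = 0.01       # m
REFERENCE_AORTIC_ROOT_AREA = _circle_area(0.012)
REFERENCE_MPA_AREA = _circle_area(0.008)
REFERENCE_SHUNT_LENGTH = 0.02        # m
REFERENCE_SHUNT_K = 1.5              # entrance + tee-junction order


@dataclass(frozen=True)
class PatientGeneratorConfig:
    """Seeded sampling plan for virtual patients.

    ``resistance_cv`` is the coefficient of variation of the log-normal
    multiplicative perturbation applied to each reference resistance.
    Ranges are inclusive (lo, hi) bounds sampled uniformly; a degenerate
    range (lo == hi) pins the value.
    """

    seed: int = 0
    resistance_cv: float = 0.2
    area_range: dict[str, tuple[float, float]] = field(default_factory=dict)
    asymmetry_range: tuple[float, float] = (0.8, 1.25)
    shunt_k_range: tuple[float, float] = (0.5, 3.0)

    def __post_init__(self):
        if self.resistance_cv < 0:
            raise ConfigError(f"resistance_cv must be >= 0, got {self.resistance_cv}")
        for label, (lo, hi) in (("asymmetry_range", self.asymmetry_range),
                                ("shunt_k_range", self.shunt_k_range)):
            if not (0 < lo <= hi) and not (label == "shunt_k_range" and 0 <= lo <= hi):
                raise ConfigError(f"{label} must satisfy 0 < lo <= hi, got ({lo}, {hi})")
        for name, (lo, hi) in self.area_range.items():
            if name not in OUTLET_NAMES:
                raise ConfigError(f"unknown vessel {name!r} in area_range")
            if not 0 < lo <= hi:
                raise ConfigError(
                    f"area_range[{name}] must satisfy 0 < lo <= hi, got ({lo}, {hi})"
                )


def reference_patient(shunt_diameter: float = 0.004) -> PatientNetwork:
    """The deterministic network with exactly the published constants."""
    outlets = tuple(
        OutletBC(
            name=name,
            resistance=REFERENCE_RESISTANCES_MPA[name] * MPA_S_M3_TO_PA_S_M3,
            area=REFERENCE_AREAS[name],
            porous_length=REFERENCE_POROUS_LENGTH,
        )
        for name in OUTLET_NAMES
    )
    return PatientNetwork(
        blood=BloodProperties(density=REFERENCE_DENSITY,
                              viscosity=REFERENCE_VISCOSITY),
        outlets=outlets,
        shunt=ShuntSpec(diameter=shunt_diameter,
                        length=REFERENCE_SHUNT_LENGTH,
                        minor_loss_coefficient=REFERENCE_SHUNT_K),
        lpa_rpa_asymmetry=1.0,
        aortic_root_area=REFERENCE_AORTIC_ROOT_AREA,
        mpa_area=REFERENCE_MPA_AREA,
    )


def generate_patient(config: PatientGeneratorConfig) -> PatientNetwork:
    """Draw one virtual patient; identical config (incl. seed) is bit-stable.

    Resistances: R_i = R_ref,i * LogNormal(mu, sigma) with sigma chosen so
    the multiplicative factor has coefficient of variation ``resistance_cv``
    and unit mean (mu = -sigma^2/2).
    """
    rng = np.random.default_rng(config.seed)
    cv = config.resistance_cv
    sigma = math.sqrt(math.log1p(cv * cv))
    mu = -0.5 * sigma * sigma

    outlets = []
    for name in OUTLET_NAMES:
        factor = float(rng.lognormal(mean=mu, sigma=sigma)) if cv > 0 else 1.0
        lo, hi = config.area_range.get(
            name, (REFERENCE_AREAS[name], REFERENCE_AREAS[name])
        )
        outlets.append(
            OutletBC(
                name=name,
                resistance=REFERENCE_RESISTANCES_MPA[name]
                * MPA_S_M3_TO_PA_S_M3 * factor,
                area=float(rng.uniform(lo, hi)),
                porous_length=REFERENCE_POROUS_LENGTH,
            )
        )

    asym = float(rng.uniform(*config.asymmetry_range))
    k = float(rng.uniform(*config.shunt_k_range))
    return PatientNetwork(
        blood=BloodProperties(density=REFERENCE_DENSITY,
                              viscosity=REFERENCE_VISCOSITY),
        outlets=tuple(outlets),
        shunt=ShuntSpec(diameter=0.004, length=REFERENCE_SHUNT_LENGTH,
                        minor_loss_coefficient=k),
        lpa_rpa_asymmetry=asym,
        aortic_root_area=REFERENCE_AORTIC_ROOT_AREA,
        mpa_area=REFERENCE_MPA_AREA,
    )
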