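"""Outlet-resistance calibration against clinical pressure targets.

The systemic outlets form a single parallel bank discharging the aortic
node to the reference pressure, so matching a mean arterial pressure (MAP)
and a per-outlet flow-fraction vector at a given total systemic flow has
the closed-form solution R_i = MAP / (f_i * Q_S).  Pulmonary resistances
are never touched: the downstream pulmonary vascular resistance is held
fixed across the design grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidArgumentError
from .hemo_network import SYSTEMIC_OUTLETS, FlowSolution
from .units import mmhg_to_pa, pa_to_mmhg


@dataclass(frozen=True)
class ClinicalTargets:
    """Clinical pressures (mmHg) and target systemic flow distribution."""

    systolic_pressure: float
    diastolic_pressure: float
    target_flow_fractions: dict[str, float] = field(default_factory=dict)
    pressure_tolerance: float = 0.05

    def __post_init__(self):
        if not self.systolic_pressure > self.diastolic_pressure > 0:
            raise InvalidArgumentError(
                "need systolic > diastolic > 0, got "
                f"{self.systolic_pressure}/{self.diastolic_pressure}"
            )
        if self.target_flow_fractions:
            if set(self.target_flow_fractions) != set(SYSTEMIC_OUTLETS):
                raise InvalidArgumentError(
                    f"fractions must cover exactly {SYSTEMIC_OUTLETS}"
                )
            total = sum(self.target_flow_fractions.values())
            if abs(total - 1.0) > 1e-12:
                raise InvalidArgumentError(
                    f"flow fractions must sum to 1 (got {total!r})"
                )
            if any(not 0.0 < f < 1.0 for f in self.target_flow_fractions.values()):
                raise InvalidArgumentError("each flow fraction must lie in (0, 1)")

    @property
    def mean_pressure_mmhg(self) -> float:
        return mean_arterial_pressure(self.systolic_pressure, self.diastolic_pressure)

    @property
    def mean_pressure_pa(self) -> float:
        return mmhg_to_pa(self.mean_pressure_mmhg)


def mean_arterial_pressure(systolic: float, diastolic: float) -> float:
    """MAP = diastolic + pulse pressure / 3 (mmHg in, mmHg out)."""
    if diastolic <= 0 or systolic < diastolic:
        raise InvalidArgumentError(
            f"need systolic >= diastolic > 0, got {systolic}/{diastolic}"
        )
    return diastolic + (systolic - diastolic) / 3.0


def fractions_from_resistances(resistances: dict[str, float]) -> dict[str, float]:
    """Flow fractions implied by parallel resistances: f_i proportional 1/R_i."""
    conductances = {k: 1.0 / r for k, r in resistances.items()}
    g_total = sum(conductances.values())
    return {k: g / g_total for k, g in conductances.items()}


def calibrate_outlet_resistances(targets: ClinicalTargets,
                                 systemic_flow: float) -> dict[str, float]:
    """Resistances (Pa.s/m^3) reproducing MAP and the flow fractions.

    ``systemic_flow`` is the total systemic flow (m^3/s) at the calibration
    operating point.  Exact by the single-node parallel identity
    R_i = MAP / (f_i * Q_S).
    """
    if systemic_flow <= 0:
        raise InvalidArgumentError(
            f"systemic_flow must be > 0, got {systemic_flow}"
        )
    if not targets.target_flow_fractions:
        raise InvalidArgumentError("targets carry no flow fractions to calibrate to")
    map_pa = targets.mean_pressure_pa
    out = {}
    for name, frac in targets.target_flow_fractions.items():
        if frac <= 0:
            raise InvalidArgumentError(
                f"zero/negative fraction for {name} implies infinite resistance"
            )
        out[name] = map_pa / (frac * systemic_flow)
    return out


def pressure_match_error(solution: FlowSolution,
                         targets: ClinicalTargets) -> float:
    """|model systemic pressure - clinical MAP| / clinical MAP (fraction).

    Acceptance against ``targets.pressure_tolerance`` is the caller's check.
    """
    model_mmhg = pa_to_mmhg(solution.aortic_pressure)
    clinical = targets.mean_pressure_mmhg
    return abs(model_mmhg - clinical) / clinical
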