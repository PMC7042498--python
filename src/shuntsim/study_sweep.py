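"""The 35-case design sweep: 5 shunt diameters x 7 stenosis ratios.

Cardiac output depends on shunt diameter only (a larger shunt unloads the
single ventricle into a lower-resistance circuit), via an exact lookup
table; stenosis severity does not alter CO.  Each case is solved
independently, so grid order cannot change per-case values, and rows are
emitted diameter-ascending then alpha-ascending.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import pandas as pd

from .energetics_metrics import (
    CaseReport,
    flow_splits,
    power_loss,
    relative_power_loss,
)
from .errors import (
    InvalidArgumentError,
    PhysiologicInfeasibleError,
    ReversedShuntError,
    SolverError,
)
from .hemo_network import (
    PULMONARY_OUTLETS,
    SYSTEMIC_OUTLETS,
    CaseDefinition,
    PatientNetwork,
    build_case_network,
    solve_steady,
)
from .oxygen_transport import OxygenParameters, oxygen_report
from .shunt_hydraulics import reynolds_number
from .units import l_min_to_m3_s, m3_s_to_ml_min

logger = logging.getLogger(__name__)

#: Diameter (mm) -> cardiac output (L/min); exact published table.
CO_TABLE_L_MIN = {3.0: 2.122, 3.5: 2.303, 4.0: 2.458, 4.5: 2.630, 5.0: 2.798}

GRID_DIAMETERS_MM = (3.0, 3.5, 4.0, 4.5, 5.0)
GRID_ALPHAS = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30)

CSV_COLUMNS = [
    "diameter_mm", "alpha", "qp_qs", "q_lpa_rpa", "pl_mW", "rpl_pct",
    "do2_ml_min", "cart", "cven", "re_shunt", "residual_kg_s", "status",
]


@dataclass(frozen=True)
class SweepGrid:
    """The design grid and its per-diameter cardiac-output table."""

    diameters_mm: tuple[float, ...] = GRID_DIAMETERS_MM
    alphas: tuple[float, ...] = GRID_ALPHAS
    co_table_l_min: dict[float, float] = field(
        default_factory=lambda: dict(CO_TABLE_L_MIN)
    )
    allow_interpolation: bool = False

    def __post_init__(self):
        missing = [d for d in self.diameters_mm if d not in self.co_table_l_min]
        if missing and not self.allow_interpolation:
            raise InvalidArgumentError(
                f"co_table_l_min missing diameters {missing}"
            )

    @property
    def n_cases(self) -> int:
        return len(self.diameters_mm) * len(self.alphas)


def cardiac_output_for_diameter(diameter_mm: float,
                                grid: SweepGrid | None = None) -> float:
    """Cardiac output (L/min) for a shunt diameter, by exact table lookup.

    Interpolation between table entries is only performed when the grid was
    built with ``allow_interpolation=True``.
    """
    grid = grid or SweepGrid()
    table = grid.co_table_l_min
    if diameter_mm in table:
        return table[diameter_mm]
    if not grid.allow_interpolation:
        raise InvalidArgumentError(
            f"no cardiac output tabulated for diameter {diameter_mm} mm "
            "(set allow_interpolation to interpolate)"
        )
    ds = sorted(table)
    if not ds[0] <= diameter_mm <= ds[-1]:
        raise InvalidArgumentError(
            f"diameter {diameter_mm} mm outside table range [{ds[0]}, {ds[-1]}]"
        )
    for lo, hi in zip(ds, ds[1:]):
        if lo <= diameter_mm <= hi:
            w = (diameter_mm - lo) / (hi - lo)
            return table[lo] * (1 - w) + table[hi] * w
    raise AssertionError("unreachable")


def run_case(patient: PatientNetwork, case: CaseDefinition,
             oxygen_params: OxygenParameters | None = None) -> CaseReport:
    """Solve one case and evaluate every metric.

    Oxygen-infeasible regimes are returned with ``status='o2-infeasible'``
    and the hemodynamic metrics intact; solver failures propagate as
    :class:`SolverError` with the case identity attached.
    """
    oxygen_params = oxygen_params or OxygenParameters()
    network = build_case_network(patient, case)
    d_mm = round(case.shunt_diameter * 1e3, 9)  # kill mm<->m round-off
    try:
        solution = solve_steady(network)
    except (SolverError, ReversedShuntError) as exc:
        exc.args = (
            f"case d={d_mm:g} mm alpha={case.alpha:g}: {exc.args[0]}",
        ) + exc.args[1:]
        raise

    qp_qs, q_lpa_rpa = flow_splits(solution)
    pl = power_loss(solution)
    rpl = relative_power_loss(solution)
    re_shunt = reynolds_number(
        solution.element_flows["shunt"], network.shunt.diameter, solution.blood
    )
    q_pul = sum(solution.outlet_flow(n) for n in PULMONARY_OUTLETS)
    q_sys = sum(solution.outlet_flow(n) for n in SYSTEMIC_OUTLETS)

    status, detail, oxy = "ok", "", None
    try:
        oxy = oxygen_report(
            m3_s_to_ml_min(q_pul), m3_s_to_ml_min(q_sys), oxygen_params
        )
    except PhysiologicInfeasibleError as exc:
        status, detail = "o2-infeasible", str(exc)

    logger.info(
        "case d=%g mm alpha=%g: residual=%.3e kg/s iterations=%d",
        d_mm, case.alpha, solution.residual, solution.iterations,
    )
    return CaseReport(
        diameter_mm=d_mm,
        alpha=case.alpha,
        qp_qs=qp_qs,
        q_lpa_rpa=q_lpa_rpa,
        power_loss_mw=pl,
        relative_power_loss_pct=rpl,
        reynolds_shunt=re_shunt,
        oxygen=oxy,
        mass_residual_kg_s=solution.residual,
        iterations=solution.iterations,
        status=status,
        detail=detail,
    )


def run_grid(patient: PatientNetwork, grid: SweepGrid | None = None,
             oxygen_params: OxygenParameters | None = None) -> list[CaseReport]:
    """Run every grid case; failed cases become rows, never omissions."""
    grid = grid or SweepGrid()
    reports = []
    for d_mm in grid.diameters_mm:
        co = l_min_to_m3_s(cardiac_output_for_diameter(d_mm, grid))
        for alpha in grid.alphas:
            case = CaseDefinition(
                shunt_diameter=d_mm * 1e-3, alpha=alpha, cardiac_output=co
            )
            try:
                reports.append(run_case(patient, case, oxygen_params))
            except (SolverError, ReversedShuntError) as exc:
                reports.append(
                    CaseReport(
                        diameter_mm=d_mm, alpha=alpha,
                        qp_qs=float("nan"), q_lpa_rpa=float("nan"),
                        power_loss_mw=float("nan"),
                        relative_power_loss_pct=float("nan"),
                        reynolds_shunt=float("nan"),
                        mass_residual_kg_s=float("nan"),
                        status="solver-failed", detail=str(exc),
                    )
                )
    return reports


def reports_to_frame(reports: list[CaseReport]) -> pd.DataFrame:
    """Flatten reports into the fixed CSV schema (one row per case)."""
    rows = []
    for r in reports:
        rows.append({
            "diameter_mm": r.diameter_mm,
            "alpha": r.alpha,
            "qp_qs": r.qp_qs,
            "q_lpa_rpa": r.q_lpa_rpa,
            "pl_mW": r.power_loss_mw,
            "rpl_pct": r.relative_power_loss_pct,
            "do2_ml_min": r.oxygen.do2 if r.oxygen else float("nan"),
            "cart": r.oxygen.c_art if r.oxygen else float("nan"),
            "cven": r.oxygen.c_ven if r.oxygen else float("nan"),
            "re_shunt": r.reynolds_shunt,
            "residual_kg_s": r.mass_residual_kg_s,
            "status": r.status,
        })
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def run_metadata(patient_config: dict, seed: int | None = None,
                 version: str | None = None) -> dict:
    """Provenance sidecar: config hash, seed and package version."""
    from . import __version__
    blob = json.dumps(patient_config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "version": version or __version__,
    }
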