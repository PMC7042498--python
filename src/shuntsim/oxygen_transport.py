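"""Steady-state oxygen mass balance of the parallel shunt circulation.

Two balances close the model: the lungs load oxygen into the pulmonary
flow (Qp * Cart + uptake = Qp * Cpv) and the body extracts it from the
systemic flow (Qs * Cart - Qs * Cven = consumption).  With uptake equal to
consumption the systemic oxygen delivery collapses to a function of the
flow ratio r = Qp/Qs and cardiac output alone:

    DO2 = CO * Cpv / (1 + r) - CVO2 / r          [mL O2 / min]

All flows in this module are in mL/min and contents in mL O2 / mL blood,
matching the published constants (Cpv = 0.2112, CVO2 = 18 mL O2/min).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidArgumentError, PhysiologicInfeasibleError


@dataclass(frozen=True)
class OxygenParameters:
    """Pulmonary venous O2 content and whole-body consumption/uptake.

    Uptake is constrained equal to consumption (steady state), so only
    ``cvo2`` is stored.
    """

    c_pv: float = 0.2112    # mL O2 / mL blood
    cvo2: float = 18.0      # mL O2 / min

    def __post_init__(self):
        if not 0.0 < self.c_pv < 0.3:
            raise InvalidArgumentError(f"c_pv must lie in (0, 0.3), got {self.c_pv}")
        if self.cvo2 <= 0:
            raise InvalidArgumentError(f"cvo2 must be > 0, got {self.cvo2}")

    @property
    def svo2(self) -> float:
        """Lung oxygen uptake, equal to consumption at steady state."""
        return self.cvo2


@dataclass(frozen=True)
class OxygenReport:
    """Contents, delivery and flows for one case (mL, mL/min units)."""

    c_art: float
    c_ven: float
    do2: float
    qp_qs: float
    q_systemic: float
    q_pulmonary: float


def arterial_content(pulmonary_flow: float,
                     params: OxygenParameters | None = None) -> float:
    """Systemic arterial O2 content from the lung balance.

    C_art = C_pv - CVO2 / Q_P, with Q_P in mL/min.

    Raises :class:`PhysiologicInfeasibleError` when the pulmonary flow is
    too low to carry the required uptake (C_art <= 0).
    """
    params = params or OxygenParameters()
    if pulmonary_flow <= 0:
        raise InvalidArgumentError(
            f"pulmonary_flow must be > 0, got {pulmonary_flow}"
        )
    # boundary checked on the product to be exact at Q_P = CVO2 / C_pv
    if pulmonary_flow * params.c_pv <= params.cvo2:
        raise PhysiologicInfeasibleError(
            f"arterial O2 content <= 0 at Q_P = {pulmonary_flow} mL/min: "
            "total uptake impossible"
        )
    return params.c_pv - params.cvo2 / pulmonary_flow


def venous_content(systemic_flow: float, arterial_content: float,
                   params: OxygenParameters | None = None) -> float:
    """Systemic venous O2 content from the body balance.

    C_ven = C_art - CVO2 / Q_S, with Q_S in mL/min.  Negative contents are
    raised as :class:`PhysiologicInfeasibleError`, never clipped.
    """
    params = params or OxygenParameters()
    if systemic_flow <= 0:
        raise InvalidArgumentError(f"systemic_flow must be > 0, got {systemic_flow}")
    c_ven = arterial_content - params.cvo2 / systemic_flow
    if c_ven < 0:
        raise PhysiologicInfeasibleError(
            f"venous O2 content {c_ven:.4g} < 0 at Q_S = {systemic_flow} mL/min"
        )
    return c_ven


def oxygen_delivery(qp_qs: float, cardiac_output: float,
                    params: OxygenParameters | None = None) -> float:
    """Systemic oxygen delivery DO2 (mL O2/min) at flow ratio r = Qp/Qs.

    DO2 = CO * C_pv / (1 + r) - CVO2 / r, with CO in mL/min.  Equivalent to
    Q_S * C_art with Q_S = CO/(1+r), Q_P = CO r/(1+r).
    """
    params = params or OxygenParameters()
    if qp_qs <= 0:
        raise InvalidArgumentError(f"qp_qs must be > 0, got {qp_qs}")
    if cardiac_output <= 0:
        raise InvalidArgumentError(
            f"cardiac_output must be > 0, got {cardiac_output}"
        )
    do2 = cardiac_output * params.c_pv / (1.0 + qp_qs) - params.cvo2 / qp_qs
    if do2 <= 0:
        raise PhysiologicInfeasibleError(
            f"DO2 {do2:.4g} <= 0 at Qp/Qs = {qp_qs}, CO = {cardiac_output} mL/min"
        )
    return do2


def oxygen_report(q_pulmonary: float, q_systemic: float,
                  params: OxygenParameters | None = None) -> OxygenReport:
    """Full oxygen report from the two flows (mL/min)."""
    params = params or OxygenParameters()
    c_art = arterial_content(q_pulmonary, params)
    c_ven = venous_content(q_systemic, c_art, params)
    return OxygenReport(
        c_art=c_art,
        c_ven=c_ven,
        do2=q_systemic * c_art,
        qp_qs=q_pulmonary / q_systemic,
        q_systemic=q_systemic,
        q_pulmonary=q_pulmonary,
    )
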