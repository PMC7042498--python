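"""Unit conversions used at the I/O boundary.

Everything inside the package is SI (Pa, m^3/s, Pa.s/m^3, kg/m^3).  Clinical
and published quantities arrive in mmHg, L/min, mL/min and MPa.s.m^-3; the
helpers here convert exactly once, at the boundary.
"""

MMHG_PER_PA = 1.0 / 133.322387415
PA_PER_MMHG = 133.322387415

L_PER_MIN_TO_M3_PER_S = 1.0e-3 / 60.0
M3_PER_S_TO_L_PER_MIN = 60.0e3
ML_PER_MIN_TO_M3_PER_S = 1.0e-6 / 60.0
M3_PER_S_TO_ML_PER_MIN = 60.0e6

MPA_S_M3_TO_PA_S_M3 = 1.0e6
PA_S_M3_TO_MPA_S_M3 = 1.0e-6

W_TO_MW = 1.0e3


def mmhg_to_pa(p: float) -> float:
    return p * PA_PER_MMHG


def pa_to_mmhg(p: float) -> float:
    return p * MMHG_PER_PA


def l_min_to_m3_s(q: float) -> float:
    return q * L_PER_MIN_TO_M3_PER_S


def m3_s_to_l_min(q: float) -> float:
    return q * M3_PER_S_TO_L_PER_MIN


def ml_min_to_m3_s(q: float) -> float:
    return q * ML_PER_MIN_TO_M3_PER_S


def m3_s_to_ml_min(q: float) -> float:
    return q * M3_PER_S_TO_ML_PER_MIN
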