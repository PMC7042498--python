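"""YAML patient-config round-tripping.

The on-disk format keeps the published units (resistance_MPa_s_m3, areas in
m^2, lengths in m) and the exact outlet names IA, LCA, LSA, DAO, LPA, RPA;
conversion to SI happens on load.
"""

from __future__ import annotations

import yaml

from .errors import ConfigError
from .hemo_network import (
    OUTLET_NAMES,
    BloodProperties,
    OutletBC,
    PatientNetwork,
    ShuntSpec,
)
from .units import MPA_S_M3_TO_PA_S_M3, PA_S_M3_TO_MPA_S_M3


def patient_to_dict(patient: PatientNetwork) -> dict:
    return {
        "blood": {
            "density_kg_m3": patient.blood.density,
            "viscosity_Pa_s": patient.blood.viscosity,
        },
        "outlets": {
            o.name: {
                "resistance_MPa_s_m3": o.resistance * PA_S_M3_TO_MPA_S_M3,
                "area_m2": o.area,
                "porous_length_m": o.porous_length,
            }
            for o in patient.outlets
        },
        "shunt": {
            "diameter_m": patient.shunt.diameter,
            "length_m": patient.shunt.length,
            "minor_loss_coefficient": patient.shunt.minor_loss_coefficient,
        },
        "lpa_rpa_asymmetry": patient.lpa_rpa_asymmetry,
        "aortic_root_area_m2": patient.aortic_root_area,
        "mpa_area_m2": patient.mpa_area,
        "reference_pressure_Pa": patient.reference_pressure,
    }


def patient_from_dict(data: dict) -> PatientNetwork:
    try:
        blood = BloodProperties(
            density=data["blood"]["density_kg_m3"],
            viscosity=data["blood"]["viscosity_Pa_s"],
        )
        outlets = tuple(
            OutletBC(
                name=name,
                resistance=data["outlets"][name]["resistance_MPa_s_m3"]
                * MPA_S_M3_TO_PA_S_M3,
                area=data["outlets"][name]["area_m2"],
                porous_length=data["outlets"][name]["porous_length_m"],
            )
            for name in OUTLET_NAMES
        )
        shunt = ShuntSpec(
            diameter=data["shunt"]["diameter_m"],
            length=data["shunt"]["length_m"],
            minor_loss_coefficient=data["shunt"]["minor_loss_coefficient"],
        )
        return PatientNetwork(
            blood=blood,
            outlets=outlets,
            shunt=shunt,
            lpa_rpa_asymmetry=data.get("lpa_rpa_asymmetry", 1.0),
            aortic_root_area=data["aortic_root_area_m2"],
            mpa_area=data["mpa_area_m2"],
            reference_pressure=data.get("reference_pressure_Pa", 0.0),
        )
    except KeyError as exc:
        raise ConfigError(f"patient config missing key {exc}") from exc


def save_patient(patient: PatientNetwork, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(patient_to_dict(patient), fh, sort_keys=False)


def load_patient(path) -> PatientNetwork:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: not a mapping")
    return patient_from_dict(data)
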