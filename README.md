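# shuntsim

Desk-scale lumped-parameter (0D) hemodynamics of central (systemic-to-pulmonary)
shunts. The arterial tree is collapsed to two pressure nodes — aortic and
pulmonary — bridged by a nonlinear shunt element (Poiseuille + minor-loss law)
and drained by six resistive outlets (IA, LCA, LSA, DAO, LPA, RPA). On top of
the steady-flow solver sits the analysis layer:

- **stenosis parameterization** — the ratio α = Q_MPA/CO splits cardiac output
  between the aortic inflow `(1−α)·CO` and the antegrade pulmonary inflow
  `α·CO` (α = 0 is pulmonary atresia);
- **porous-resistance conversion** — X = R·A/(μ·l) for outlet boundary zones;
- **energetics** — power loss `PL = Σ_in (p+½ρv²)Q − Σ_out (p+½ρv²)Q` (mW) and
  relative power loss (% of inlet energy flux), cross-checked against an
  independent per-element ΔP·Q dissipation sum;
- **oxygen transport** — the steady O₂ balance giving
  `DO2 = CO·C_pv/(1+Qp/Qs) − CVO2/(Qp/Qs)`;
- **calibration** — closed-form outlet-resistance identification from a
  clinical mean arterial pressure (MAP = DBP + PP/3) and a systemic
  flow-fraction vector, with a pressure-match check;
- **the design sweep** — 5 shunt diameters (3–5 mm) × 7 stenosis ratios
  (0–30 %), cardiac output assigned per diameter from a fixed table, written
  to a CSV/JSON result table with a provenance sidecar;
- **virtual patients** — seeded generation of patient parameter sets
  (log-normal resistance perturbations, uniform areas/asymmetry/loss
  coefficients) around the built-in reference patient.

Internally everything is SI (Pa, m³/s); published units (mmHg, L/min,
MPa·s·m⁻³) are converted at the I/O boundary.

## CLI

```bash
shuntsim case --diameter 4 --alpha 0.15           # one grid point, JSON metrics
shuntsim sweep --out results.csv --json results.json   # full 35-case grid
shuntsim do2 --qp-qs 1.01 --co-l-min 2.122        # oxygen delivery, mL O2/min
shuntsim bc convert -r 131 -a 1e-5 -l 0.01        # porous viscous coefficient
shuntsim synth --seed 42 --out patient.yaml       # virtual patient config
shuntsim calibrate --targets targets.yaml --qs-l-min 1.06
shuntsim sweep --config patient.yaml --out results.csv  # sweep that patient
```

`targets.yaml` needs `systolic_pressure_mmHg` / `diastolic_pressure_mmHg` and
optionally `target_flow_fractions` (defaults to the fractions implied by the
reference resistances). Patient YAML files carry the six outlets by name with
`resistance_MPa_s_m3`, `area_m2`, `porous_length_m`.

## Library quick start

```python
from shuntsim import (CaseDefinition, build_case_network, reference_patient,
                      run_grid, reports_to_frame, solve_steady)
from shuntsim.units import l_min_to_m3_s

patient = reference_patient()
case = CaseDefinition(shunt_diameter=0.004, alpha=0.15,
                      cardiac_output=l_min_to_m3_s(2.458))
solution = solve_steady(build_case_network(patient, case))
print(solution.aortic_pressure, solution.element_flows["shunt"])

table = reports_to_frame(run_grid(patient))   # the full 35-case table
```

## Scope notes

This is a steady-state, rigid-wall, two-node surrogate: no 3D/1D spatial
discretization, no turbulence closure, no pulsatility. Flow-split and power
numbers from 3D CFD are reproduced in *trend* (Qp/Qs rises with diameter and
α; DO₂ and PL fall with α), not in value. Infeasible oxygen regimes and
reversed shunt flow raise typed errors / flagged rows rather than being
clamped or dropped.
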