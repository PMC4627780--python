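# odmgrowth

Oxygen-driven modelling of xenograft tumour growth: forward simulation,
parameter estimation from longitudinal tumour-volume studies, and
practical-identifiability diagnostics.

## The problem

Subcutaneous xenografts are the workhorse of preclinical oncology, but
their growth curves are usually summarised empirically, with no link to
the pathophysiology (perfusion, hypoxia, necrosis) that drives response to
therapy.  This package implements a mechanistic alternative: an avascular
spherical tumour fed by oxygen diffusing in from the periphery, in which
oxygen — a surrogate for everything the vasculature delivers — drives
proliferation, and its depletion towards the core produces hypoxic and
necrotic regions.  It is aimed at modellers and DMPK scientists who fit
tumour growth curves, design xenograft studies, or need hypoxia/necrosis
predictions from calliper data alone.

## The model

Steady-state diffusion with first-order uptake gives the radial oxygen
profile P(r) = P_b·cosh(kR′·r)/cosh(kR′·rT), with rT = V_T^(1/3) and a
boundary tension that falls with exposed surface area,
P_b = P_O2^max·(V_To/V_T)^(2/3).  The sphere is discretised into n
material shells with equal oxygen drop per shell, so the tension at shell
index i is

    P_O2,i = P_O2^max / (n·cosh(kR′·rT)) · (V_To/V_T)^(2/3) · (n − i + i·cosh(kR′·rT)).

Each shell grows as dV_i/dt = k_p·P_O2,i·V_i, and hypoxic/necrotic
volumes are saturable partitions V_i·K/(K+P_O2,i) with switch constants
K_H > K_N.  Four parameters carry the biology: k_p ((mmHg·day)⁻¹,
cell-line-intrinsic proliferation), kR′ (cm⁻¹, lumped oxygen
uptake/perfusion), K_H and K_N (mmHg).  A stroma extension adds a
recruited compartment V_S that multiplies the growth term.

Fits minimise the region-weighted least squares
Σ_r Σ_t (V̂_{t,r} − V_{t,r})²/N_r over regions r ∈ {T, H, N} with 150
latin-hypercube multi-starts; identifiability is diagnosed from the SVD of
the normalised sensitivity matrix (collinearity index γ = 1/σ_last,
condition number κ = σ_1/σ_last, Fisher-information rank).  See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
from odmgrowth import (ModelParams, StudyDesign, FitConfig,
                       simulate, generate_study, fit)

params = ModelParams(kp=0.0058, kRp=13.37, KH=25.9, KN=20.2)

# forward simulation: 0.1 cm3 tumour over six weeks
traj = simulate(params, 0.1, np.linspace(0, 40, 41))
print(f"day 40: VT={traj.VT[-1]:.2f} VH={traj.VH[-1]:.2f} VN={traj.VN[-1]:.2f} cm3")

# synthetic 10-animal study with weekly hypoxia/necrosis, then refit
study = generate_study(params, StudyDesign(noise_cv=0.10), seed=1)
result = fit(study, FitConfig(n_starts=150, seed=1))
print({k: round(v, 4) for k, v in result.estimates.items()})
print(f"objective = {result.objective:.4f}")
```

prints

```
day 40: VT=1.79 VH=1.44 VN=1.36 cm3
{'kp': 0.0059, 'kRp': 15.7092, 'KH': 23.9496, 'KN': 18.026}
objective = 0.0001
```

By day 40 the 1.8 cm³ tumour is ~80% hypoxic and ~76% necrotic — the
poorly-oxygenated core dominates, which is exactly the regime where
longitudinal hypoxia/necrosis data make all four parameters practically
identifiable.  The refit recovers the generating parameters to within the
noise of a single 10-animal study (k_p within 2%, the others within
~10–20%); medians across replicate studies land tighter, which is what
the acceptance script measures.

The same workflow is scriptable from the shell:

```bash
odm simulate sim.yaml -o trajectory.csv
odm synth synth.yaml -o study.csv --seed 1
odm fit study.csv --config fit.yaml -o fit.json
odm identify design.yaml -o report.json
odm fixtures T3 --summary
```

`odm fixtures` exposes the packaged reference tables of fitted parameters
for 38 xenografted cell lines, 5 explant-like models and the
stroma-extended fit.

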