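# Methods

## The model

`odmgrowth` implements an oxygen-driven model of subcutaneous xenograft
growth.  The tumour is an avascular sphere fed by oxygen diffusing in from
the surrounding tissue; oxygen, as a surrogate for everything the
vasculature delivers, drives proliferation, and its depletion towards the
core produces hypoxia and necrosis.

**Oxygen profile.**  Steady-state Fick diffusion with first-order cellular
uptake in a sphere gives

    P(r) = P_b · cosh(kR'·r) / cosh(kR'·rT),

with `kR'` (cm⁻¹) the *apparent oxygen uptake rate*, √(k_R/D) scaled by
(3/4π)^(1/3).  Folding the geometric factor into `kR'` lets the model use
`rT = VT^(1/3)` as its radius surrogate, so no 4π/3 factors appear in any
shell geometry.  The boundary tension falls with exposed surface area as
the tumour outgrows its initial volume,

    P_b = Pmax · (VTo/VT)^(2/3),     Pmax = 60 mmHg by default

(60 mmHg is a representative peritumoural epithelial oxygen tension; real
values span roughly 30–104 mmHg, so `Pmax` is configurable).

**Shell discretisation.**  The sphere is split into `n` concentric,
*material* shells: each keeps its identity for all time, and only its
oxygen assignment is recomputed from the current total volume (the
quasi-steady-state limit of oxygen equilibrating much faster than cell
division).  Shell boundaries are placed where the continuous profile takes
equally spaced values — exponentially spaced radii, dense near the rim —
so the oxygen *drop* per shell is constant and the discretised tension is
linear in the shell index:

    P_i = P_b/(n·cosh(kR'·rT)) · (n − i + i·cosh(kR'·rT)),  i = 0..n.

All cosh ratios are evaluated in exponent-difference (sech/tanh) form, so
the equations remain finite for `kR'·rT` of several hundred (fitted `kR'`
values above 100 cm⁻¹ do occur).

**Growth, hypoxia, necrosis.**  Each shell grows as dVi/dt = kp·P_i·Vi.
Hypoxic and necrotic volumes are algebraic saturable partitions of each
shell, Vi·K/(K+P_i), with switch constants K_H and K_N (mmHg); they are
computed at output times, never integrated.

**Stroma extension.**  A well-mixed stromal compartment V_S is recruited
in proportion to tumour volume (dV_S/dt = k_S·ΣVi) and multiplies the
growth term (dVi/dt = k_PG·P_i·Vi·V_S).  With k_S = 0 and V_S = 1 the
extension reduces exactly to the base model.

## Design choices where the design was open

**Switch orientation.**  The partition written as `P/(K+P)` *increases*
with oxygen, which contradicts the semantics of hypoxia and necrosis as
consequences of oxygen deprivation (fully anoxic tissue would be entirely
viable).  The default is therefore the complement form `K/(K+P)`, under
which the affected fraction tends to 1 as oxygen vanishes and, with
K_N < K_H, necrotic tissue is always a subset of hypoxic tissue.  The
mirror form remains available as `orientation="as_printed"`.

**Which oxygen value drives a shell.**  The discretised profile is linear
in the index, so a shell between boundaries i−1 and i may be driven by the
tension at its outer boundary or at its centre index i−1/2.  The
outer-boundary choice is first-order accurate in shell count: growth
curves for n = 10 vs n = 20 still differ by ~4% on the reference
parameter set.  The shell-centre value is second-order (0.25% for the same
comparison) and is the default (`oxygen_index="mid"`); the outer-boundary
convention is available as `oxygen_index="outer"`.  Default `n_shells` is
5; a convergence check over n ∈ {1, 2, 5, 10, 20} is part of the test
suite.

**Initial shell volumes.**  VTo is partitioned by the equal-drop radii at
t = 0, Vi(0) = r_i³ − r_{i−1}³.  When `kR'·rT` is below 1e−6 the
equal-drop construction degenerates (flat profile) and equal-volume
boundaries r_i = rT·(i/n)^(1/3) are used, keeping behaviour continuous as
`kR' → 0`.

## Numerics

Integration uses LSODA (`scipy.integrate.odeint`) with a hand-derived
analytic Jacobian of the shell equations (verified against finite
differences in the tests); dense output is interpolated to requested
times, and solver steps are never forced onto observation times.
Default tolerances are rtol 1e−8 / atol 1e−10 for forward simulation and
rtol 1e−7 / atol 1e−9 during fitting (the best fit is re-evaluated at the
tight tolerance).  The analytic `kR' → 0` limit,
VT(t) = VTo·(1 + (2/3)·kp·Pmax·t)^(3/2), and an independent fixed-step RK4
integration serve as oracles; halving tolerances changes the endpoint
volume by under 1e−6 relative.  Late-time growth of the base model
follows this t^(3/2)-type law (sub-exponential, asymptotically driven by
kp and kR'); no linear asymptote is asserted.

## Estimation

The objective is the region-weighted least squares

    OF(θ) = Σ_r Σ_t (V̂_{t,r} − V_{t,r})² / N_r,   r ∈ {T, H, N},

where N_r is the number of records per region; the per-region averaging
makes a 4-point hypoxia series commensurate with a 13-point volume series.
(The source formulation prints the residual without the square; the
squared form is the only reading consistent with least squares and with
nonnegative reported residuals, and is what is implemented.)

Animals are pooled by fitting the per-time-point mean volume
(`pooling="mean"`, default; `"pooled"` fits every record).  Mixed-effects
modelling of inter-animal variability is out of scope.  VTo is taken from
the first observed volume unless overridden.  Multi-start optimisation
draws 150 latin-hypercube starts (default) over box bounds
kp ∈ [1e−5, 0.1] (mmHg·day)⁻¹, kR' ∈ [0.1, 100] cm⁻¹,
K_H, K_N ∈ [0.1, 200] mmHg — spanning all reported fits with margin — and
runs a bounded trust-region-reflective least-squares minimiser from every
start (max 500 function evaluations, objective tolerance 1e−10).  A
failed simulation at a trial point returns a large finite penalty so the
optimiser can continue.

**Standard errors.**  Calliper-derived volumes carry multiplicative
noise: the residual standard deviation grows with the measured volume.
The default (`error_model="proportional"`) therefore uses the
weighted-least-squares sandwich covariance for sd_m = c·Y_m, with the
relative noise level c estimated from the relative residuals.  In
simulation this estimator is calibrated (empirical sd / reported SE
between 0.9 and 1.2 across replicates), whereas the classical
homoscedastic estimator σ̂²·FIM⁻¹ with σ̂² = OF/(n−p) underestimates the
sampling spread by 1.4–1.7× under the same noise; the classical form
remains available as `standard_errors()` / `error_model="additive"`.

## Identifiability

Sensitivities S_{mj} = ∂Ŷ_m/∂θ_j are central finite differences with
relative step 1e−6 (Richardson-extrapolated step-halving is the test
oracle); a forward-sensitivity backend (`method="forward"`) integrates
the augmented ODE for kp and kR′ — including the kR′-dependence of the
equal-drop initial shell partition — with analytic output partials for
K_H/K_N, and agrees with the differences to ~1e−8.  The dimensionless S̃ = S·θ/Y is factorised by SVD; the
collinearity index γ = 1/σ_last and condition number κ = σ_1/σ_last are
flagged against γ < 10 and κ < 1000.  The Fisher information matrix is
S̃ᵀS̃ (the inverse-based expression sometimes written for the FIM is not
defined for non-square S), and its numerical rank — eigenvalues above
1e−8 of the largest — counts practically identifiable parameters.  The
rank is computed from the *normalised* matrix: raw sensitivities mix
units (kp ~ 5e−3, K_H ~ 26), so the raw eigenvalue spread reflects
parameter scale rather than information; the raw matrix is retained for
covariances.  Only practical identifiability is covered; structural
(symbolic) identifiability is out of scope.

## Synthetic studies

`synthetic.generate_study` emulates subcutaneous xenograft efficacy
studies: per-animal take volumes lognormal around 0.1 cm³ (CV 20%),
calliper measurements 1–3 times weekly over 28 days (default Mon/Wed/Fri),
multiplicative lognormal measurement noise (default CV 15%,
mean-corrected so observations are unbiased; no reported noise magnitude
exists for such studies, so 15% is a preclinical convention), and
optional hypoxic/necrotic volume observations weekly (sacrificial
cohorts), at end of study only (HIF1α-style endpoints), or not at all.
Calliper volumes use the prolate-spheroid convention L·W²/2.

What the generator does **not** emulate: animal dropout and welfare
culling, treatment effects, measurement operator effects, inter-animal
parameter variability (all animals share the ground-truth kinetics; only
take volume and noise vary), and spatially realistic hypoxia/necrosis
readouts (region volumes are generated from the model's own partitions).
Passing recovery tests therefore demonstrate internal consistency of
estimation under realistic sampling and noise — not that the model is
correct for any real cell line.

## Problem sizes used in tests and the acceptance script

Parameter-recovery experiments use 10 animals, 28–30 day studies and 10
seeded replicates (150 starts each) for the headline recovery, and 50
replicates with 6 starts for coverage/robustness properties; these sizes
give stable medians while keeping the full suite quick to run.

## Known limitations

* One-dimensional spherical geometry; no 3-D or image-derived shapes.
* Diffusive oxygen transport only; no convection or carrier transport.
* No treatment/drug effects.
* Mean-curve pooling ignores inter-animal kinetic variability; reported
  SEs describe measurement noise around a shared curve.
* The stroma extension is a single well-mixed compartment with linear
  recruitment; it is marginally identifiable from growth curves alone.
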