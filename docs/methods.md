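# Methods

This document describes the models implemented in `apaptox`, their
parameters, the numerical schemes, and the known limitations. Units
throughout: concentrations in µM (doses in mg/kg or mM where stated), time
in minutes, lengths in µm, cell volumes in µm³, body-scale volumes in mL,
amounts in µmol.

## 1. Single-hepatocyte pharmacodynamic model (`pd_cell`)

Each hepatocyte is a well-mixed reaction volume with seven state variables:
intracellular APAP `A`, NAPQI `N`, GSH `G`, mitochondrial protein adducts
`D`, ROS `R`, active JNK fraction `J`, and ATP `P`. Four cumulative
bookkeeping states (`cum_uptake`, `cum_ugt`, `cum_sult`, `cum_cyp`, in µM
of cell volume) close the mass ledger.

Fluxes:

- **Passive uptake** `v_up = P_m · S / V_c · (C_ext − A)` with membrane
  permeability `P_m` (µm/min), surface `S` (µm²), volume `V_c` (µm³).
- **Conjugation** by UGT and SULT, and **oxidation** to NAPQI by CYP2E1
  and CYP1A2, all Michaelis–Menten in `A`.
- **NAPQI detoxification** by GST at rate
  `v_gst = Vmax_gst · N/(Km,N + N) · g`, where `g = G/(Km,G + G)` is the
  GSH availability fraction; consumed GSH is stoichiometric with
  detoxified NAPQI.
- **Adduct formation** `k_adduct · N · (1 − g)`: NAPQI escaping
  detoxification binds mitochondrial proteins.
- **GSH turnover** `dG/dt = k_gsh · (gsh0 − G) − v_gst − k_clear · R · G`
  (resynthesis toward baseline, consumption by GST, oxidation by ROS).
- **ROS production** is a Hill function of adducts,
  `k_ros · D^n / (k_half^n + D^n)`, amplified `(1 + a_jnk · J)`-fold by
  active JNK; ROS is cleared first-order via the GSH term above.
- **JNK activation** `dJ/dt = k_jnk_act · R · (1 − J) − k_jnk_deact · J`.
- **MPT and death**: when ROS exceeds `ros_crit` the mitochondrial
  permeability transition (MPT) is latched irreversibly and ATP production
  stops; ATP then decays as `−k_atp_use · P`. A cell is dead when
  `P < atp_death` (strict), also latched. Death is detected on the output
  grid (default 1 min), so death times are grid-quantised.

Default parameters (µM, min):

| parameter | value | | parameter | value |
|---|---|---|---|---|
| permeability | 10 µm/min | | k_adduct | 0.1 /min |
| surface | 2000 µm² | | k_ros | 6 µM/min |
| volume | 8000 µm³ | | n_ros (Hill) | 2 |
| vmax_ugt / km_ugt | 500 / 1500 | | k_ros_half | 500 µM |
| vmax_sult / km_sult | 120 / 300 | | a_jnk | 4 |
| vmax_cyp2e1 / km | 18 / 1000 | | k_jnk_act | 0.02 /(µM·min) |
| vmax_cyp1a2 / km | 135 / 1500 | | k_jnk_deact | 0.05 /min |
| vmax_gst | 200 | | k_clear | 1e-3 /(µM·min) |
| km_gst_napqi | 50 | | ros_crit | 30 µM |
| km_gst_gsh | 500 | | k_atp_prod | 100 µM/min |
| gsh0 | 7000 µM | | k_atp_use | 0.02 /min |
| k_gsh | 6e-3 /min | | atp0, atp_death | 5000, 100 µM |

The exposure `C_ext(t)` is an `ExposureProfile` (constant, linear decay,
or sampled) for in vitro wells, or the co-integrated blood/medium
compartment in the coupled models.

## 2. Population model (`population`)

A population couples two sources of heterogeneity:

- **Zonation.** Each cell carries a normalised lobule position
  `z ∈ [0, 1]` (0 = pericentral, 1 = periportal). In vitro populations
  draw `z` stratified-uniformly; lobule populations take `z` from network
  geometry. Given positivity fractions `f` (defaults: CYP2E1 0.509,
  CYP1A2 0.605), the `round(f·n)` cells with smallest `z` are positive —
  this pins the realised fraction to within one cell and makes the
  CYP2E1⁺ region nested inside the CYP1A2⁺ region by construction. With
  the default `linear` gradient, positive cells get a Vmax ramping
  linearly from the pericentral maximum at `z = 0` to zero at the
  positivity cutoff (the marginal cell keeps an infinitesimal Vmax so
  positivity flags and capacities agree).
- **Random variability.** Six parameters (`vmax_ugt`, `vmax_sult`,
  `vmax_gst`, `k_gsh`, `k_ros`, `k_atp_prod`) are drawn per cell from
  mean-preserving lognormals with coefficient of variation 0.3. Each
  cell's initial ATP is its own production/consumption fixed point
  `k_atp_prod / k_atp_use`.

`simulate_invitro` integrates all cells against a shared well
concentration and returns the dead-fraction curve; the reduced 160-cell
ensemble reproduces the full 3251-cell ensemble's 24 h dead fraction to
within the 5 pp tolerance (acceptance target t3).

## 3. Classical PK and extrapolation (`pk_classical`)

Intraperitoneal dosing is the closed-form two-compartment (Bateman)
model: absorption `k_a` from the peritoneum (bioavailability `f_bio`),
elimination `k_el` from a blood volume `v_blood`. Defaults: `k_a` 0.08
/min, `f_bio` 0.9, `v_blood` 14 mL, `k_el` 0.018 /min, body weight 25 g.
The degenerate case `k_a ≈ k_el` uses the `t·e^{−kt}` limit.

Classical in vitro → in vivo extrapolation maps each in vivo dose to an
exposure summary (Cmax, or AUC/T as a time-averaged concentration) and
reads toxicity off the in vitro concentration–response table by
log₁₀-concentration interpolation (clamped with a warning outside the
measured range). `fit_pk` estimates `(k_a, k_el, v_blood)` by
log₁₀-space least squares with `f_bio` fixed (it is not identifiable
from blood data alone).

## 4. Coupled whole-body models (`coupled_models`)

The CL-2/CL-3 variants co-integrate blood and peritoneum compartments
with the representative cell ensemble; CL-3 adds first-order non-liver
clearance `k_nonliver` (default 0.003 /min), and an optional ECM storage
pool. The representative ensemble of `n` cells is upscaled to the whole
liver by the factor `n_lobule · 3215 / n` (default `n_lobule` 3.0e4
lobules of 3215 hepatocytes). A discrete µmol ledger (peritoneum, blood,
intracellular, conjugates, CYP-oxidised, non-liver, ECM) is tracked and
must close to 1e-4 of the dose (it closes to ~1e-15 in practice);
violation raises `FloatingPointError`. `elimination_split` reports the
terminal fate fractions; the projected non-liver share
(non-liver / total eliminated) converges to the plateau share used for
acceptance target t7.

CL-1 is the uncoupled variant: the exogenous closed-form PK curve drives
the ensemble, and diagnostics report the implied hepatic uptake as a
fraction of the bioavailable dose plus a `consistency_ratio` that flags
when the neglected uptake is not actually negligible (it is not, for the
default parameters — the motivation for CL-2/3).

`dose_response_invivo` integrates each dose to the horizon (default 480
min) and carries the dead fraction forward to 24 h when the toxicity
curve has plateaued (slope < 0.1 pp/h).

## 5. Spatial lobule model (`lobule`)

- **Geometry.** A synthetic ring/spoke sinusoid network: 6 portal inlets
  on a 300 µm lobule radius, 6 concentric rings, 36 spokes, stochastic
  circumferential/cross connections, radii 4.5 ± 0.5 µm (min 2),
  tortuosity 1.3. Hepatocytes (default 3215) are placed along edges in
  `n_layers` = 10 plates; each cell's `z` is its normalised network
  distance from the central vein.
- **Blood rheology.** Effective viscosity uses the Pries
  Fåhræus–Lindqvist in vitro fit
  `η₄₅(d) = 220·e^{−1.3d} + 3.2 − 2.44·e^{−0.06·d^{0.645}}`
  (d in µm, relative to plasma), generalised to other hematocrits via the
  `C(d)` shape function.
- **Flow.** Poiseuille conductances `g = πr⁴/(8ηL)` assembled into a
  sparse nodal Kirchhoff system, driven by either total inflow (default
  7.2e-5 mL/min per lobule) or inlet pressure. Residuals close to 1e-10.
- **Transport.** Finite-volume upwind advection on edge segments
  (target 25 µm), with precomputed sparse operators and CFL-limited
  substeps; hepatocyte exchange and cell dynamics advance by Lie
  splitting (transport ↔ cell RK4 steps between 1-min latch updates).
  Mass balance closes to 1e-12 (pure advection) / 1e-6 (with cells).
- **ST body model.** The lobule is embedded in the closed loop
  peritoneum → blood → `n_lobule` identical lobules → blood, with
  non-liver clearance on blood; bookkeeping is discrete and
  ledger-exact. Total liver flow is `Q_liver = n_lobule · q_lobule`
  (default 2.16 mL/min); sensitivity analyses vary `Q_liver` through
  `n_lobule` at fixed per-lobule flow, which matches the upscaling
  convention and avoids conflating flow with intra-lobule residence
  time.

A 2000 µM constant-inlet simulation of the default lobule depletes a
passage to ≈ 0.905 of the inlet; compounded over the ≈ 30 passages a
tracer makes in 7.5 min (15 s per passage), ≈ 5 % remains — the
residence-time anchor (acceptance criterion 1).

## 6. Calibration (`calibration`)

- **In vitro → in vivo scaling**: CYP2E1 ×3.3, CYP1A2 ×1.8, GSH baseline
  ×0.5 (`scale_to_invivo`, idempotence-guarded).
- **Likelihood**: Gaussian with profiled variance,
  `ℓ = −n/2 · (ln(2π·mse) + 1)`.
- **Optimiser**: a compact, seeded (µ/µ_w, λ)-CMA-ES (rank-1 + rank-µ
  covariance updates, cumulative step-size adaptation, box projection),
  searching in log₁₀ parameter space with bounds of ±`bounds_scale`
  (default 4×) around the initial point. Validated on a 5-D sphere to
  1e-10.
- **Strategies**: STR2 fits the in vitro model, then the classical PK,
  then runs the uncoupled CL-1 (reporting its self-consistency
  violation); STR3 fits in vitro then the CL-2 body sequentially; STR4
  fits cell and body parameters jointly against toxicity + PK data. The
  in vitro objective stacks all concentrations into one tiled ensemble
  integration for speed.
- **Non-liver constraint**: blood PK alone cannot identify the split
  between hepatic and non-hepatic clearance, so the body objective adds
  a quadratic penalty pulling the projected non-liver share toward the
  published 15 %. The `FitSpec` default weight (200) is a weak
  regulariser; the acceptance pipeline uses 1e5, at which the constraint
  binds (shares 13.6–15.7 % across seeds).
- **Sensitivity screen**: one-at-a-time ×factor/÷factor perturbations of
  the mean-cell parameters, flagged against a percentage-point threshold
  on a caller-supplied endpoint. With a 10× factor and 5 pp threshold on
  the in vivo endpoint, `permeability`, `vmax_cyp2e1`, `km_cyp2e1`,
  `km_gst_gsh` and `n_ros` are insensitive while `vmax_cyp1a2`, `gsh0`
  and `k_ros` are strong drivers.

## 7. Synthetic data (`fixtures`)

`inpaper` serves the numeric anchors printed in the source study's text
(dose panels, sampling times, positivity fractions, scaling factors),
each with its citation context. Figure-level raw data are never
transcribed; instead `SyntheticDesign` generates datasets from a known
ground truth: in vitro dead fractions with binomial counting noise
(`n_per_well` = 500) plus Gaussian assay noise (sd 0.02) over 3
replicates, and PK curves with 10 % lognormal CV. Setting the noise
parameters to zero yields exact model outputs for recovery tests.

## 8. Numerics

- **Ensemble integrator**: fixed-step RK4 over the output grid (default
  1 min), vectorised across cells and numba-JIT-compiled (numpy
  fallback). The substep count per grid interval is
  `ceil(grid_dt · λ / 2)` where `λ` is an a-priori bound on the fastest
  linear rate (membrane equilibration, MM slopes, JNK/ATP rates). MPT
  and death latches are frozen within each grid interval and updated on
  the grid, so both are detected with grid resolution.
- **Single-cell reference**: `simulate_cell` uses LSODA
  (rtol 1e-6 / atol 1e-9) and is the oracle the RK4 path is tested
  against.
- **Known limitation — post-commitment JNK stiffness.** In MPT-latched,
  death-committed cells ROS can grow to O(10³) µM, and the JNK activation
  rate `k_jnk_act · R` then exceeds the stability bound assumed by the
  substep heuristic. The fixed-step RK4 is locally unstable there:
  post-commitment GSH/ROS/JNK values can deviate from the adaptive
  reference. This is endpoint-irrelevant — death times, APAP, ATP and
  all cumulative ledgers match LSODA over 24 h at 4 mM (regression
  tested) — because MPT latching at 30 µM ROS and the subsequent ≈195
  min ATP rundown decide death long before ROS is large. We accept the
  artefact rather than slow every simulation 3–18×.
- **Conservation checks**: every compartment model carries a discrete
  µmol ledger; closure tolerances are enforced at runtime (coupled
  models) and in tests (1e-4 required, ~1e-6…1e-15 observed).

## 9. Limitations

- The ring/spoke lobule is an idealisation: it reproduces topology,
  perfusion scale and zonation, but its pressure drop and mean
  sinusoidal velocity cannot simultaneously match the study's printed
  anchors (~113 Pa and ~47 µm/s) at the stated per-lobule flow. The
  flow solver is therefore validated against exact Poiseuille/Kirchhoff
  oracles, and flow-sensitivity conclusions are drawn from relative
  comparisons only.
- Death detection is grid-quantised (1 min default).
- `f_bio` is fixed in PK fits (unidentifiable from blood data).
- The classical extrapolation clamps outside the measured in vitro
  concentration range (with a warning) rather than extrapolating.
- Post-commitment GSH/ROS/JNK trajectories are qualitative (see §8).
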