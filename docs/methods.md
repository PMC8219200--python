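# Methods

This note records the model, its assumptions, the calibrated and tunable
parameters, and the design choices made where the design was genuinely
open.  It is the companion to the module docstrings; nothing here states a
result the test suite or `scripts/acceptance.py` does not itself compute.

## Scope and overall structure

The package emulates a patient-specific CFD deposition study of two
extrafine combination pMDIs in 20 COPD patients at desk scale.  Three
stages are chained: a synthetic cohort (demographics, lung and lobar
volumes, scaled airway morphometry), a reduced-order deposition surrogate,
and the descriptive/inferential statistics.  Out of scope by design: image
segmentation and meshing, 3D Navier–Stokes CFD with Lagrangian tracking,
scintigraphy-style planar C:P ratios, mucociliary clearance, and any
exhaled-fraction modelling (the closure assumes every inhaled particle
deposits; in vivo the exhaled fraction of extrafine aerosol is a few
percent).

## Virtual cohort

Demographic targets (defaults): 15 M / 5 F; age 64.0 ± 7.68 y; height
168.9 ± 8.40 cm; FEV1 42.3 ± 14.8 % predicted, truncated to [25, 80]
(moderate-to-severe obstruction).  Draws are truncated normals affinely
rescaled so the cohort *sample means equal the targets exactly* (the SD is
matched before the bounds are re-imposed, so it is approximate).  This
exact-moment contract is deliberate and is reused by the other
generators: reported cohort-level inputs are treated as constraints, not
merely as distribution parameters.

Lung volumes: TLC from ECSC height/sex prediction equations times a
hyperinflation factor 1.08; FRC/TLC = 0.75 − 0.002·FEV1% (air trapping
rises as FEV1 falls) with jitter SD 0.03, clipped to [0.45, 0.85].  Lobar
inspiratory shares default to RUL 0.20, RML 0.09, RLL 0.25, LUL 0.21,
LLL 0.25 with additive jitter (SD 0.015, renormalised); expiratory lobar
volumes apply the patient FRC/TLC ratio with 5 % per-lobe jitter and are
rescaled to sum to FRC.  Lobar expansion is uniform within a lobe by
assumption, and each lobe's share of inspired flow equals its share of
total expansion.

The airway tree is a published-style symmetric 24-generation morphometry
table (Weibel-type diameters/lengths; branching and gravity angles in the
style of typical-path whole-lung models), shipped as
`src/aerodep/data/morphometry.csv` at a reference volume of 4.8 L.  Per
patient it is scaled isotropically by `(TLC/4.8)^(1/3)`.  Generations
whose scaled diameter falls below the central cut-off (default 0.2 cm,
the conservative end of the 1–2 mm HRCT resolution limit; configurable)
are peripheral and are further narrowed by an obstruction factor
`min(1, 0.4 + 0.6·FEV1/100)` — monotone in FEV1 and exactly 1 for an
unobstructed lung.  Because of the peripheral closure rule (below), the
narrowing affects geometry exports but not the regional totals.

## Inhalation profiles

Both profile kinds are half-sine waveforms (single-peaked, smooth, zero
at both ends; peak = π/2 × mean).  The waveform shape is a design choice;
the deposition efficiencies consume only the mean flow, the waveform is
kept for volume bookkeeping.  The *optimal* profile is 4.5 s at exactly
30 L/min (2.25 L inhaled).  *Measured* profiles sample inspiratory volume
(lognormal, median 1.5 L, GSD 1.35) and time (lognormal, median 3.0 s,
GSD 1.25, clipped to [1.5, 6] s) — medians/GSDs chosen as realistic COPD
values since the source distributions are not tabulated — then shrink the
implied mean flows affinely about 29.35 L/min so the cohort mean is exact
and every profile lies inside [16.15, 68.83] L/min.  Profiles pair with
patients by index (severity-matched, not same-patient, as in the
emulated design).  Exhalation is not modelled.

## Aerosol and dose accounting

Per API the nominal dose splits exactly into device retention
(`1 − DD/nominal`), coarse delivered mass (`(1 − FPF)·DD/nominal`) and
fine mass (`FPF·DD/nominal`).  The coarse, ballistic fraction deposits
entirely in the extrathoracic region — the same convention by which
cascade impaction assigns non-FPF mass to the induction port.  The fine
PSD is lognormal(MMAD, GSD) over 40 log-spaced bins in [0.05, 20] um,
truncated at the 5 um FPF cut-off (standard impactor convention; the
cut-off is not published for these measurements) and renormalised.
Nominal doses: BDP 100 ug, FF 6 ug, and GB 12.5 ug per actuation.  The GB
nominal is not published and remains configurable; 12.5 ug makes the mean
DD/nominal of the triple product equal 86.1 %, exactly consistent with
the published ET+IT total.  Plume shot mass and cone angle are carried in
the data model and reports but do not enter the surrogate; only the
100 mm ejection velocity (throat distance) and, for reporting, duration
are used.

## Deposition surrogate

Air properties at 37 °C: μ = 1.9e-5 Pa·s, mean free path 0.070 um,
Cunningham slip `1 + Kn(1.257 + 0.4·exp(−1.1/Kn))`, unit density for
aerodynamic diameter.

Mouth-throat: per bin, `eta = I/(1+I)` with
`I = k_et·d²·(Q̄ + k_plume·v₁₀₀)` — monotone in size, flow, and plume
momentum.  The surviving fine PSD (bin-wise attenuated, so the in-lung
distribution is size-shifted) splits over lobes by expansion fraction and
marches generation by generation; per-airway flow is lobe flow divided by
the generation's airway count.  Efficiencies per generation:

* impaction: `P = 1 − (2/π)acos(θ·Stk) + (1/π)sin(2·acos(θ·Stk))` for
  `θ·Stk < 1` (θ = branching angle, radians), else 1;
* sedimentation: laminar Poiseuille inclined-tube result in
  `k = 3 v_s sin(γ) L / (4 ū D)` (γ = angle between airway axis and
  gravity), `P = (2/π)[2k√(1−k^⅔) − k^⅓√(1−k^⅔) + asin(k^⅓)]`, clamped at
  1 — verified against a 10⁵-particle Monte-Carlo tracking oracle with
  flux-weighted inlets to within 2 % (agreement is typically < 1 %);
* diffusion: Gormley–Kennedy series in `μ = D_B L / Q`, with the
  small-μ expansion below 0.009.

In central generations the *impaction term only* is multiplied by
`k_central` (then clamped) before the three mechanisms combine as
independent survival probabilities.  This is the one place the package
deviates from scaling the combined probability: the enhancement the
calibration absorbs — turbulent laryngeal jet, secondary flows at
cartilaginous rings, cross-sectional irregularity — acts on inertial
capture, not on gravity or Brownian motion.  Empirically the choice
matters: scaling the combined probability inflates sedimentation at low
flow and inverts the optimal-versus-measured ordering of the C:P ratio,
whereas impaction-only scaling reproduces the published ordering and
magnitudes out of sample.  Mass passing the last central generation
deposits in that lobe's peripheral region; the balance
`ET + central + peripheral = 100·DD/nominal` holds to 1e-9 (a residual
float drift below ~1e-12 is folded back into ET).

Calibration: `(k_et, k_plume, k_central)` are fitted in log space
(trust-region least squares, hence positive by construction) so the dual
product's cohort means match ET 55.9, IT 28.1 and C:P 0.62 at measured
flow, with the C:P residual weighted ×10 so a 0.01 ratio miss counts like
0.1 percentage points.  Because conservation ties ET+IT to the product's
mean DD/nominal (84.17 % vs the published 84.0), the ET/IT residuals
cannot both vanish; they settle near ±0.08 pp.  ET depends on `k_et` and
`k_plume` only through one effective combination at a given flow
distribution, so the fitted pair is identified only up to that trade-off;
the fit is deterministic (fixed start: 2e-3, 2.0, 400) and predictions
are insensitive to the split because the two products' plume velocities
differ by only ~18 %.  With the constants frozen, every triple-product
quantity is an out-of-sample prediction.

## Metrics and statistics

Regional summaries are mean ± sample SD (n−1).  C:P is computed per API
as central/peripheral and averaged (arithmetic by default; geometric
available) over the product's APIs per patient.

The ratio model is `log(dep) ~ product * flow + api` with a per-patient
random intercept (REML via statsmodels MixedLM).  The product×flow
interaction is included because the target of inference is the product
contrast *at each flow*, estimated-marginal-mean style; without it the
two per-flow ratios would be forced equal.  For exactly log-additive
input (e.g. the deterministic surrogate's table) the residual variance is
~0 and REML degenerates; the model then falls back to within-patient OLS
(patient fixed effects), which yields the identical contrast in this
balanced design.  Satterthwaite denominator df for the product-at-flow
contrast reduce, in the balanced paired layout, to the within-patient
residual df `N − n_patients − (p − 1)` (= 136 for the full table); this
closed form matches R `lmerTest`/`emmeans` (Satterthwaite and
Kenward–Roger) in the cross-check test.  A pure fixed-effects variant is
available via `method="fixed"`.

TOST: per API × region × flow, the per-patient `log(triple/dual)` ratios
are tested one-sided against log 0.80 and log 1.25 at α = 0.05;
equivalence requires both rejections (equivalently max one-sided p <
0.05).  Both the two-sided 95 % CI (as published) and the classical 90 %
TOST interval are reported.  No multiplicity adjustment is applied.

## Synthetic paired cohort for the statistics

The statistics machinery is exercised on a generator calibrated to the
product-specific log-scale outcomes: dual-product central/peripheral
geometric means derive from its intrathoracic level and C:P per flow
(measured: 28.1 %, 0.62; optimal: 27.3 %, 0.65); triple-product cells are
the dual cells times the per-API central/peripheral ratios (measured:
BDP 0.92/1.20, FF 0.94/1.21; optimal: BDP 0.97/1.24, FF 0.99/1.25).
Intrathoracic values are the row-wise sum central + peripheral, so the
regional identity holds exactly.  Variance components: patient intercept
SD 0.18 (matching the ~18 % between-patient coefficient of variation of
intrathoracic deposition) and per-cell residual SDs 0.057 (central) and
0.069 (peripheral), back-calculated from the published 95 % CI widths of
the paired ratios at n = 20.  By default the sampled intercepts and
residuals are mean-centred per cell — the generator-wide exact-moment
contract — so the recovered ratios are stable for any seed; property
tests that study genuine sampling behaviour (interval coverage, TOST
type-I error at the boundary) disable centring.

## Numerical choices and problem sizes

40 PSD bins (mass median within 1 % of the MMAD from 20 bins up); GSD
floor 1 + 1e-9 for the monodisperse limit; truncated-bin mass split
uniformly in log diameter; all probabilities clamped to [0, 1];
degenerate groups (single observation) reported with SD 0 and flagged.
Study-scale runs use the published cohort size n = 20 throughout;
property simulations use 10⁵ Monte-Carlo particles for the settling
oracle, 500 replicates for interval coverage, and 2000 for the TOST
type-I check.  All randomness flows from explicit seeds
(`numpy.random.default_rng`; the acceptance script spawns child seeds
from one `SeedSequence`), and pipeline outputs are byte-identical across
re-runs of the same config.

## What passing tests do and do not show

The cohort, profiles, and synthetic statistics table emulate published
summary statistics, not patient-level data: lobar volume distributions,
within-patient correlation structure, and flow-profile shapes are
plausible but unvalidated, so agreement with the published regional means
demonstrates that the surrogate plus calibration reproduces the study's
accounting and its product contrast — not that it would predict an
individual patient's deposition.  The triple-product predictions are out
of sample with respect to the calibration but share the virtual cohort
with it.  The sedimentation oracle validates one mechanism in isolation;
the impaction and mouth-throat correlations are standard functional forms
whose constants are absorbed by calibration rather than independently
verified.  C:P comparisons use the 3D airway-tree definition of
central/peripheral and are not comparable to planar scintigraphy ROI
ratios.
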