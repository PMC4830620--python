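# Methods

## Model and assumptions

The package simulates a deterministic four-state kinetic model of
amyloid-driven neurodegeneration and RXR-agonist treatment in APP/PS1
mice. States: healthy brain cells N and diseased brain cells Nd (number
per volume, normalized to 100 healthy cells at age 2 months), soluble
Aβ42 load A (pmol per mg protein) and bexarotene-induced unbound ApoE
P₀ (per volume).

Assumptions inherited from the model's construction:

* Healthy↔diseased conversion is Michaelis–Menten in the amyloid load,
  k_d(A) = λ_d A/(A+α_d), with the recovery rate its complement
  k_h = λ_d − k_d: conversion is conservative, and the *sum* of forward
  and reverse rates is constant. Diseased cells die irreversibly at
  μ_d; dead ("damaged") cells are the absorbing complement of N+Nd and
  carry no state variable.
* Amyloid production is proportional to Nd² + Nd·N. This is the lumped
  form of "production scales with APP×secretase abundance" after
  assuming both scale with cell counts, that healthy cells carry
  negligible APP relative to diseased cells, and equal secretase
  density in both cell classes. The mechanistic species (APP,
  γ-secretase, RXR, background ApoE) are eliminated symbols absorbed
  into the lumped constants k_A and k_B; they are deliberately not
  represented at runtime.
* Only drug-induced ApoE is tracked: P₀ grows at k_B·N·B(t) (healthy
  cells produce it under drug stimulation) and is consumed
  stoichiometrically with amyloid at k_P0·A·P₀.
* The drug level B(t) (mg/kg body mass) is exogenous: it resets to the
  dose B₀ at each administration t_B + nL and decays exponentially at
  r between doses (pulsed mode); constant mode holds B ≡ B₀ from t_B.
  "Constant" dosing is a true constant level, not a high-frequency
  pulse limit (the two agree in the L→0 limit; a unit test pins this).

Units are lumped exactly as in the parameter definitions (e.g. k_B in
kg·mg⁻¹·day⁻¹ bridges the mg/kg drug level and per-volume cell counts);
quantities are plain floats with units documented in the docstrings,
with no runtime unit algebra.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| λ_d | max healthy→diseased conversion rate | 6.1·10⁻² | day⁻¹ |
| α_d | half-saturation amyloid load | 17 | pmol·mg⁻¹ |
| μ_d | diseased-cell death rate | 5·10⁻³ | day⁻¹ |
| k_A | amyloid production constant | 3.5·10⁻⁴ | pmol·(mg·day·vol²)⁻¹ |
| k_P0 | ApoE–amyloid removal rate | 4.4·10⁻² | vol·day⁻¹ |
| k_B | drug→ApoE production rate | 5·10⁻² | kg·mg⁻¹·day⁻¹ |
| r | drug elimination rate | 15.26 | day⁻¹ |

Initial conditions at age 2 months: N=100, Nd=0, A=0.25 pmol·mg⁻¹,
P₀=0. Two printed unit inconsistencies in the source tables were
resolved in favour of dimensional consistency: α_d shares A's unit
(pmol·mg⁻¹; the rate law requires it), and k_P0 is per *day* like every
other rate (its table-of-symbols entry says per hour, but the
simulation value is day-based).

Time convention: 1 month = 30 days, with the model clock starting at
age 2 months (so a six-month-old mouse has been simulated for 120 days
before treatment). The source never states a convention; 30 days is
the simplest and is exposed as `DAYS_PER_MONTH`.

## Numerics

* Integration: LSODA, rtol 1e−8 / atol 1e−10 by default, restarted at
  every dose instant so the B(t) discontinuity always falls on a
  segment boundary. The system is only mildly stiff, but r = 15.26
  day⁻¹ makes the drug-forced ApoE equation fast relative to the
  cellular rates (5·10⁻³–6.1·10⁻² day⁻¹); a stiffness-switching method
  is robust at negligible cost.
* The ODEs preserve non-negativity analytically; integrator output is
  clamped at zero, and any component below −1e−8 raises an integration
  error (it signals solver failure, not model behaviour).
* Output grids are uniform (0.5 day default; 0.01 day inside treatment
  windows) plus all dose instants, so the per-dose ApoE sawtooth is
  resolved.
* A fixed-step classical RK4 solver with dose-aligned steps (1e−3 day)
  serves as a brute-force oracle in tests only; the adaptive and
  fixed-step paths agree to better than 1e−5 relative on life courses
  with and without treatment.
* Threshold searches (critical dose, equivalent dose) use plain
  bisection at 1 and 0.1 mg/kg resolution respectively; dose sweeps
  default to 0 plus 101 log-spaced doses. Untreated burn-in states are
  cached (keyed on the parameters that can influence an untreated
  solve), which makes repeated threshold evaluations cheap.
* Fitting explores parameter space with a deterministic log-spaced
  grid (configurable points per decade, 8 by default) followed by
  Nelder–Mead refinement in log-parameter space from the best grid
  point; objective evaluations that fail to integrate return a 1e12
  penalty with a warning rather than raising. Identical data and
  settings give bit-identical results. Fitting-stage solves use rtol
  1e−6 / atol 1e−8; the objectives are evaluated thousands of times
  and the looser tolerance is far below the data noise.

## Critical-dosage criteria (calibration note)

"The dose required to recover healthy brain cells" is read off the
dose–response curve of final healthy-cell concentration N_f(B₀) after a
14-day course. The curve is sigmoidal and the reading convention is not
uniquely determined, so three criteria are implemented:

* `net_recovery` (API default): smallest dose with N at the end of the
  treatment window ≥ N at its start. Parameter-free and the most
  literal reading. Gives 14 / 52 / 144 mg/kg at ages 4 / 5 / 6 months.
* `steepest_slope`: the inflection of N_f(B₀). Gives 10 / 60 / 205.
* `elbow`: the visual knee of the curve drawn with the sweep's natural
  axis scales — the dose maximizing N_f(B₀) − (N₀/B_max)·B₀,
  equivalently where the marginal benefit dN_f/dB₀ falls to N₀/B_max
  (0.1 cells per mg/kg for the default 100-cell, 0–1000 mg/kg sweep).
  Gives 41 / 123 / 265 mg/kg at ages 4 / 5 / 6 months.

The elbow reading is the one that reproduces the published values
(~50 / ~150 / ~300 mg/kg) within their ±20% band, and is what
`scripts/acceptance.py` reports. All three criteria agree on the
qualitative conclusions: the threshold grows steeply with age, longer
treatment lowers it, and at four months recovery is reachable below
100 mg/kg daily.

## Dose equivalence

`equivalent_dose` matches regimens on final healthy-cell concentration.
With the default parameters, a constant infusion of ≈6.9 mg/kg matches
daily 100 mg/kg boluses (6-month-old, 14 days) — close to the
time-averaged exposure B₀(1−e^(−r))/r ≈ 6.6 mg/kg, i.e. constant
exposure is roughly 15–20× more dose-efficient than daily pulses — and
weekly dosing needs ≈510 mg/kg, about 5× the daily dose (≈660, about
7×, if matched on final amyloid instead). These are the package's
computed values for claims the source states as figure-read
approximations ("approximately 5", "nearly seven times"); the
acceptance tests therefore assert them within a factor of 1.5.

## Synthetic data

The generator emulates the statistical structure of the two calibration
datasets, which exist only as published figures:

* a longitudinal amyloid-load curve (monthly samples, age 2–15 months)
  = the model's untreated solve plus additive Gaussian noise (default
  σ = 0.5 pmol·mg⁻¹) truncated at zero. With default parameters the
  noiseless curve is sigmoidal with a single inflection and a lag of
  ≈3.5 months before its rapid rise;
* treated-cohort endpoints (fractional decrease in soluble Aβ42 for
  100 mg/kg daily at 6 months × {3, 7, 14} days, 9 months × 90 days,
  11 months × 7 days) plus truncated Gaussian noise (default
  σ = 0.03).

Noise magnitudes are conventions, not claims about the source assays.
Noise is observation-level only — the dynamics are deterministic, which
is the implicit error model of least-squares calibration. Passing
recovery tests on these data shows the pipeline inverts its own
generating process (identifiability + correctness of objectives and
optimizer); it does not validate the model against real measurements,
and the generator reproduces neither inter-animal variability nor any
assay-specific error structure.

Parameter recovery under this design: noiseless stage 1 recovers λ_d
and k_A to well under 1% (α_d and μ_d are weakly identified from the
load curve alone — a flat ridge trades α_d against μ_d — and recover to
~10%); noiseless stage 2 recovers k_P0 and k_B to under 5%; with
σ = 0.5 noise the median λ_d error across seeded replicates stays
below 10% (the test suite uses 9 replicates).

## Problem sizes used in tests

The test suite and acceptance script run at the scale of the original
experiments: life courses up to 390 days, treatment windows of 3–90
days, dose searches over 0–1000 mg/kg at 1 mg/kg resolution. Oracle
comparisons use 14–90-day windows and recovery tests use reduced grid
densities (3–4 points per decade), which already determine the optima
to well inside the asserted tolerances.

## Known limitations

* No uncertainty quantification: point fits only, matching the
  calibration style of the source.
* No plaque-area state: comparisons with measured plaque decreases use
  the healthy-cell percent change only.
* Cell counts are per-volume abstractions normalized to 100; no
  spatial structure, no stochastic single-cell variant.
* The month→day convention and the critical-dose reading are
  conventions chosen and documented here; conclusions that depend on
  them are flagged above.
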