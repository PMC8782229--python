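# Methods

## The measurement model

A portable accumulation chamber (PAC) run seals one animal in a chamber of
known internal volume (853 L by default) and records CH4 (ppm), O2 (%) and
CO2 (%) at three time points, nominally 0, 25 and 50 minutes after entry.
Gas accumulates (or, for O2, depletes) approximately linearly over this
window, so the flux is estimated from the first and last readings at their
*actual* recorded times:

    flux (l/h) = (C_x − C_y) / (T_x − T_y) × 60 × (V − liveweight) / D

where D = 10⁶ converts ppm and D = 100 converts percent to a volume
fraction, and the reading order (x, y) is (last, first) for the produced
gases and (first, last) for consumed O2, making all three fluxes positive
under normal physiology. The net volume term treats kilograms of animal as
liters of displaced headspace, exactly as the conversion is conventionally
applied in PAC work; no humidity or water-vapor correction is applied. The
middle reading enters only a linearity QC check: if it deviates from the
chord midpoint by more than 10 % (configurable) of the total change the
record is flagged `nonlinear_trace`, not dropped. Negative fluxes are
flagged and preserved — downstream estimators see them — because no
exclusion rule is part of the method.

The daily mass extrapolation is

    g/d = flux × (P × 0.1) / (8.3145 × (T + 273.15)) × M × 1440

with pressure in hPa, temperature in °C and molar masses 16/44/32 g/mol for
CH4/CO2/O2. Dimensionally the 1440 min/d factor pairs oddly with an l/h
flux (a strict reading would use l/min or a 24 h/d factor), but this is the
form in which the conversion is used and reported for PAC data, and
evaluated verbatim it reproduces the published daily-mass values from the
published mean fluxes to within 1–2 %. It is therefore implemented exactly
as written and documented here rather than "corrected"; callers who want a
strict ideal-gas conversion can compose their own from the constants
module.

## Synthetic trials

The generator emulates the motivating study's design: `n_animals` ewe lambs
(default 48) measured on `n_days` consecutive days (default 17), divided
each day into `n_runs_per_day` runs (default 4) of `n_chambers` chambers
(default 12), with assignment to runs and chambers re-randomized daily.
Per gas, the true flux of animal i on day j is

    y_ij = μ + a_i + d_j + e_ij,
    a_i ~ N(0, σ²_animal),  d_j ~ N(0, σ²_day),  e_ij ~ N(0, σ²_error),

drawn independently across gases. Default means and variance triples are
the study's reported values (CH4 0.0094 l/h with components 1.8e-6 /
3.0e-6 / 7.7e-6; O2 0.3582 with 0.0056 / 0.0069 / 0.0051; CO2 0.2194 with
0.0014 / 0.0023 / 0.0021), so the generator's defaults *are* the study
conditions. Liveweight is drawn once per animal (46 ± 4 kg) and held
constant across the 17 days, matching the single reported mean ± SD;
ambient temperature, pressure and humidity are drawn per day-run around
the reported trial means (8.33 ± 2.45 °C, 1000.05 ± 15.79 hPa,
76.68 ± 8.66 %). One master seed feeds five documented substreams (truth
effects, animal roster, environment, chamber assignment, reading noise),
so identical seeds give identical trials.

Traces are constructed by inverting the flux equation from ambient
baselines (CH4 2.0 ppm, O2 20.9 %, CO2 0.04 % — typical outdoor air; only
differences enter the flux equations, so the choice is inconsequential
downstream), with the 25-min reading placed on the chord. Reading-level
instrument noise and reading-time jitter are available but default to
zero, which makes generation → flux conversion an exact inverse pair
(verified to 1e-10 l/h).

What the generator does *not* emulate: within-chamber mixing dynamics,
chamber leakage, diurnal emission cycles, feed-intake effects, any
dependence of flux on the simulated environment covariates, cross-gas
correlation of the random effects, and the strictly positive support of
real fluxes (the Gaussian CH4 tail occasionally implies a negative chamber
reading; such draws are rejected with a diagnostic, or dropped as missed
measurements under `on_invalid="drop"`, which the pipeline uses). Passing
tests on synthetic data therefore validate the estimators under the
additive-model assumptions, not the physics of a real chamber.

## Variance components

`fit_anova_balanced` is the closed-form method-of-moments solution for the
balanced crossed design with one record per cell: σ̂²_e = MS_error,
σ̂²_animal = (MS_animal − MS_error)/n_days, σ̂²_day = (MS_day −
MS_error)/n_animals, negatives truncated to zero and flagged. Its standard
errors use the chi-square sampling variances of the independent mean
squares. It exists both as a user-facing fast path and as an independent
oracle for the iterative estimator.

`fit_reml` maximizes the restricted log-likelihood of y = Xβ + Z_a a +
Z_d d + e. All likelihood quantities are computed from cross-products via
the Woodbury identity, so an evaluation costs O(q³) in the number of
random-effect levels (65 for the default design) regardless of record
count, and missing animal-day cells need no special handling. The response
is standardized internally so the same optimizer settings serve variances
spanning 1e-6 (CH4) to 1e-2 (O2). Optimization is direct bounded
maximization (L-BFGS-B on the variance scale, balanced-ANOVA starting
values where the layout permits, convergence at relative log-likelihood
change below ~1e-13 with a projected-gradient fallback check). An EM-type
scheme was considered and rejected: the direct search reaches the same
optimum — it matches the balanced-ANOVA closed form to better than 1e-6
relative on interior solutions — with simpler boundary handling.
Components that converge onto the zero boundary are truncated, flagged,
and the reduced model refitted for the reported likelihood. If the
*residual* variance collapses onto its floor (a perfect-fit degeneracy,
possible with noise-free synthetic data where the restricted likelihood is
unbounded), the fit is returned as a flagged boundary solution with the
remaining components profiled at the pinned floor. Standard errors come
from the inverse observed-information matrix (central-difference Hessian)
at the optimum; they are reported as NaN for boundary components, where
the quadratic approximation is invalid.

Derived summaries: H_ani = σ²_a/(σ²_a+σ²_d+σ²_e); CV = σ_a/μ with μ the
sample mean flux; repeatability defaults to σ²_a/(σ²_a+σ²_e) from the
model with liveweight and humidity as fixed covariates and animal + date
random. The published repeatability values cannot be reproduced as any
single ratio of the published component table, so the denominator is
configurable (`"total"` adds σ²_day) and the default is documented rather
than silently chosen. Humidity is coded as a continuous covariate.
Windowed repeatability uses prefix windows (days 1..n), matching the
"consecutive days" framing. The likelihood-ratio test for dropping a
random effect uses the 50:50 boundary mixture 0.5·χ²₀ + 0.5·χ²₁ (and the
χ²_{m−1}/χ²_m mixture approximation when m > 1 components are dropped);
simulated type-I error is close to nominal.

One published inconsistency is worth recording: the CH4 row of the
component table (1.8e-6 / 3.0e-6 / 7.7e-6) implies an animal share of
14.4 % and a day share of 24 %, not the 23.08 % and ~39 % printed beside
it, while the O2 and CO2 rows are internally consistent. Worked examples
and recovery targets in the test suite are anchored on the O2 and CO2
rows for this reason.

## Precision curves

P_n = 1.96 √(σ²_e/n) is the 95 % CI range of an n-day average; the inverse
lookup returns ⌈1.96²σ²_e/target²⌉ (with a 1-ulp guard so exact hits do
not round up). Published "±" precision values mix conventions — the CH4
figures equal *half* the formula value while the O2/CO2 figures equal the
full value — so both `p_n` and `half_range = p_n/2` are always reported
and neither is guessed to be "the" precision.

## Ranking consistency

Day-pair association uses Pearson correlation (Spearman available,
off by default), pairwise-complete, with slopes and standard errors from
simple regression of the column day on the row day; R² = r² by
construction. Under the additive model the expected day-pair correlation
is the intraclass correlation σ²_a/(σ²_a+σ²_e) — day effects shift all
animals equally and cancel — which the simulation suite confirms. Tail
membership ranks animals ascending by flux within each day (ties broken by
animal id, stable; ties crossing the k-th boundary are reported), and
percentages of days are additionally rounded to the nearest integer
percent, the convention used when such counts are quoted.

## Prediction

The prediction equation fits flux on measurement day, run group and breed
(class effects, dummy-coded against a reference level) plus age,
liveweight, humidity, temperature and pressure (covariates), with a random
animal effect. Folds are stratified by animal and date: each animal's
records are dealt round-robin into folds from a rotating starting fold, so
fold sizes differ by at most one (816 records → 204/204/204/204) and every
animal with ≥ 4 records appears in ≥ 2 folds. Variance components are
re-estimated on each training fold — honest cross-validation — and
held-out records are predicted as fixed part + animal BLUP, or fixed part
only (flagged) for animals absent from training. Class levels absent from
the training fold are dropped from the design (prediction at the reference
level) and flagged per record. r² is the squared Pearson correlation of
held-out predictions and actuals, computed per fold and averaged, with the
pooled value also reported; RMSE likewise. Mean bias (predicted − actual)
is reported explicitly so scale discrepancies of the kind that can afflict
mixed-model predictions on small datasets are visible rather than hidden
in r².

## Problem sizes and numerical choices

The Monte-Carlo suites run at the sizes their conclusions need: 500
replicate 48 × 17 trials for unbiasedness of the closed-form decomposition
(< 5 % relative), 200–300 replicates for REML recovery of the O2 animal
share (observed within ~0.4 points of the 31.8 % truth), 100 random
balanced datasets for the REML/ANOVA oracle equivalence (1e-6 relative),
1000 flux-level replicates for the law-of-total-variance check, and 100
fold seeds for the null-data cross-validation check. LRT calibration runs
on smaller 12 × 8 trials, where the boundary mixture is already accurate.
Variance floors: a fitted component below 1e-8 (on the standardized scale)
is treated as zero; the residual variance has a hard floor of 1e-10.

## Known limitations

- The estimators are phenotypic throughout; no pedigree/genetic analysis.
- The trace model is two-point linear; true chamber kinetics (mixing,
  leakage, saturation) would bias real-data fluxes in ways the synthetic
  suite cannot detect.
- The prediction equation omits feed intake, the dominant driver of CH4
  output, because the emulated study design does not record it.
- The LRT mixture for dropping ≥ 2 variance components is an
  approximation; only the single-component test is simulation-calibrated.
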