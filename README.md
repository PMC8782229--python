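# pacflux

Analysis of ruminant gaseous emissions measured in **portable accumulation
chambers (PACs)** — sealed chambers in which a sheep's methane (CH4)
production, oxygen (O2) consumption and carbon dioxide (CO2) production are
spot-measured over a ~50-minute run from three concentration readings.

The package is aimed at animal scientists designing or analysing PAC
phenotyping trials: how repeatable is a single-day PAC measurement, how many
consecutive measurement days does a given precision require, how stable are
animal rankings across days, and how well can gaseous output be predicted
from routinely recorded covariates?

## What it computes

**Flux calculus.** Each chamber run yields readings at three time points
(nominally 0, 25 and 50 min after entry). The volumetric flux is the
two-point concentration change scaled by the chamber headspace:

    flux (l/h) = (C_x − C_y) / (T_x − T_y) × 60 × (V − liveweight) / D

with `D = 10⁶` for ppm-scale CH4 and `D = 100` for percent-scale O2/CO2,
and reading order chosen so production (CH4, CO2) and consumption (O2) are
both positive. The daily mass extrapolation uses the ideal-gas molar
density at the run's ambient conditions:

    g/d = flux × (P_hPa × 0.1) / (8.3145 × (T_°C + 273.15)) × M × 1440

**Variance decomposition.** Per-gas fluxes from a trial in which every
animal is measured every day follow a two-way crossed random-effects model

    y_ij = μ + animal_i + day_j + e_ij

fitted by REML (closed-form balanced ANOVA also provided as an oracle).
Derived summaries: the animal share of total variance
H_ani = σ²_a / (σ²_a + σ²_d + σ²_e), the between-animal coefficient of
variation CV = σ_a / μ, repeatability σ²_a / (σ²_a + σ²_e), prefix-window
repeatability curves, and boundary-corrected likelihood-ratio tests for the
random effects.

**Precision design curves.** The 95 % CI range of an n-day average,
P_n = 1.96 √(σ²_e / n), and the inverse lookup (days needed for a target
precision).

**Ranking consistency.** Day-pair Pearson correlations, day-on-day
regression slopes and R², and bottom-k / top-k emitter membership counts
per animal across days.

**Prediction.** A mixed-model prediction equation (day, run group and breed
as class effects; age, liveweight, humidity, temperature and pressure as
covariates; random animal effect) evaluated by 4-fold cross-validation
stratified by animal and date, reporting per-fold and averaged r² and RMSE
plus bias diagnostics.

**Synthetic trials.** A generator emulating the motivating study's design —
48 ewe lambs × 17 consecutive days, four runs of 12 chambers per day —
with additive animal/day/error variance structure per gas and traces built
by exactly inverting the flux equations, so every stage is testable without
any external data.

## Worked example

```python
from pacflux import (SimParams, simulate_trial, flux_table,
                     fit_reml, ModelSpec, precision_curve)

trial = simulate_trial(SimParams(seed=1), on_invalid="drop")
flux = flux_table(trial.trial)

vc = fit_reml(flux, ModelSpec("o2"))
print(f"O2 variance components (l/h)^2: "
      f"animal {vc.sigma2_animal:.4f}, day {vc.sigma2_day:.4f}, "
      f"error {vc.sigma2_error:.4f}")
print(f"animal share of total variance: {100 * vc.h_animal:.1f}%")
print(f"between-animal CV: {vc.cv:.2f}")

curve = precision_curve(vc.sigma2_error, n_max=17).table
print(curve[curve["n"].isin([2, 3, 7])].to_string(index=False))
```

prints

```
O2 variance components (l/h)^2: animal 0.0052, day 0.0054, error 0.0054
animal share of total variance: 32.6%
between-animal CV: 0.19
 n      p_n  half_range
 2 0.101558    0.050779
 3 0.082922    0.041461
 7 0.054285    0.027143
```

The simulated trial was generated with the study-reported oxygen variance
components (0.0056 / 0.0069 / 0.0051 (l/h)²), and one 48 × 17 realization
recovers them closely; the animal share ≈ 33 % says a third of the
variation in a single-day O2 measurement reflects stable animal
differences. The precision rows read: a 7-day average is within
±0.027 l/h (half-range) of the long-run animal mean with 95 % confidence,
versus ±0.051 l/h for a 2-day average.

The same pipeline runs from the shell:

```
pacflux run --seed 1 --output out/        # simulate → flux → varcomp →
                                          # precision → consistency → predict
pacflux simulate --config cfg.yaml        # individual stages
pacflux flux out/trial.csv --output out
pacflux varcomp out/flux.csv --output out
pacflux validate out/trial.csv
```

All stages accept a YAML config (see `pacflux.config`) and are
deterministic given a seed: rerunning with the same seed reproduces every
output byte-for-byte.

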