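"""Variance decomposition of gas fluxes across animals and days.

Per-gas fluxes from a PAC trial follow a two-way crossed random-effects
model: every animal is measured on every day, day-level shifts (weather,
feeding schedule) are shared by all animals, and what remains is residual
noise.  This module estimates the three components two ways:

* :func:`fit_anova_balanced` — the closed-form method-of-moments solution
  from the expected mean squares of the balanced one-record-per-cell
  design; exact, and independent of the iterative path.
* :func:`fit_reml` — restricted maximum likelihood for the general case
  (arbitrary fixed effects, missing animal-day cells).

From the fitted components it derives the animal share of total variance
(H_ani), the between-animal coefficient of variation CV = sd_animal / mean,
and repeatability, plus prefix-window repeatability curves and boundary-
corrected likelihood-ratio tests for the random effects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import RandomFactor, reml_fit
from .constants import check_gas

#: Aliases accepted in ModelSpec.fixed for the trial covariates.
_FIXED_ALIASES = {
    "liveweight": "liveweight_kg",
    "humidity": "humidity_pct",
    "temperature": "temp_c",
    "pressure": "pressure_hpa",
}
_RANDOM_COLUMNS = {"animal": "animal_id", "day": "day_index"}


@dataclass(frozen=True)
class ModelSpec:
    """Mixed-model specification for one gas.

    ``fixed`` lists covariate columns (aliases ``liveweight`` and
    ``humidity`` are accepted); an intercept is always included.
    ``random`` is a non-empty subset of ``("animal", "day")``.
    """

    gas: str
    fixed: tuple[str, ...] = ()
    random: tuple[str, ...] = ("animal", "day")

    def __post_init__(self) -> None:
        object.__setattr__(self, "gas", check_gas(self.gas))
        if not self.random:
            raise ValueError("at least one random effect is required")
        for r in self.random:
            if r not in _RANDOM_COLUMNS:
                raise ValueError(f"unknown random effect {r!r}")

    def fixed_columns(self) -> tuple[str, ...]:
        return tuple(_FIXED_ALIASES.get(f, f) for f in self.fixed)


#: Repeatability model of the study: liveweight and humidity as fixed
#: effects, animal and measurement date as random effects.
REPEATABILITY_SPEC_FIXED = ("liveweight", "humidity")


@dataclass
class VarComponents:
    """Fitted variance components and derived summaries for one gas."""

    gas: str
    estimator: str                      # "anova" | "reml"
    sigma2_animal: float
    sigma2_day: float
    sigma2_error: float
    se_animal: float
    se_day: float
    se_error: float
    mean_lph: float
    loglik: float
    fixed_effects: tuple[str, ...]
    truncated: tuple[str, ...] = ()
    converged: bool = True
    h_animal: float | None = None
    cv: float | None = None
    repeatability: float | None = None

    @property
    def total_variance(self) -> float:
        return self.sigma2_animal + self.sigma2_day + self.sigma2_error

    @property
    def day_share(self) -> float:
        tot = self.total_variance
        return self.sigma2_day / tot if tot > 0 else 0.0


def _gas_frame(flux: pd.DataFrame, gas: str, value: str = "flux_lph") -> pd.DataFrame:
    gas = check_gas(gas)
    df = flux[flux["gas"] == gas] if "gas" in flux.columns else flux
    if df.empty:
        raise ValueError(f"no records for gas {gas!r}")
    if df[value].isna().any():
        df = df.dropna(subset=[value])
    return df


def fit_anova_balanced(flux: pd.DataFrame, gas: str) -> VarComponents:
    """Closed-form variance components for the balanced crossed design.

    Requires every animal observed exactly once on every day.  Estimates
    come from the expected mean squares (sigma2_e = MSE,
    sigma2_animal = (MSA - MSE)/n_days, sigma2_day = (MSD - MSE)/n_animals);
    negative solutions are truncated at zero and flagged.  Standard errors
    use the chi-square sampling variance of the independent mean squares.
    """
    df = _gas_frame(flux, gas)
    wide = df.pivot_table(
        index="animal_id", columns="day_index", values="flux_lph",
        aggfunc="count", fill_value=0,
    )
    if not (wide.to_numpy() == 1).all():
        raise ValueError(
            "layout is not balanced with one record per animal-day; "
            "use fit_reml for unbalanced data"
        )
    y = df.pivot(index="animal_id", columns="day_index", values="flux_lph").to_numpy()
    a, d = y.shape
    if a < 2 or d < 2:
        raise ValueError("need at least 2 animals and 2 days")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssa = d * ((row_means - grand) ** 2).sum()
    ssd = a * ((col_means - grand) ** 2).sum()
    resid = y - row_means[:, None] - col_means[None, :] + grand
    sse = (resid**2).sum()
    dfa, dfd, dfe = a - 1, d - 1, (a - 1) * (d - 1)
    msa, msd, mse = ssa / dfa, ssd / dfd, sse / dfe

    s2e = mse
    s2a = (msa - mse) / d
    s2d = (msd - mse) / a
    truncated = []
    if s2a < 0:
        s2a, truncated = 0.0, truncated + ["animal"]
    if s2d < 0:
        s2d, truncated = 0.0, truncated + ["day"]

    se_e = np.sqrt(2 * mse**2 / dfe)
    se_a = np.sqrt(2 * (msa**2 / dfa + mse**2 / dfe)) / d
    se_d = np.sqrt(2 * (msd**2 / dfd + mse**2 / dfe)) / a

    vc = VarComponents(
        gas=check_gas(gas), estimator="anova",
        sigma2_animal=s2a, sigma2_day=s2d, sigma2_error=s2e,
        se_animal=se_a, se_day=se_d, se_error=se_e,
        mean_lph=float(grand), loglik=float("nan"), fixed_effects=(),
        truncated=tuple(truncated),
    )
    return derive_summaries(vc)


def _design(df: pd.DataFrame, spec: ModelSpec):
    cols = spec.fixed_columns()
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"fixed-effect columns missing from data: {missing}")
    X = np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(float) for c in cols]
    )
    names = ["intercept", *cols]
    factors = [
        RandomFactor.from_labels(r, df[_RANDOM_COLUMNS[r]].to_numpy())
        for r in spec.random
    ]
    return X, names, factors


def fit_reml(flux: pd.DataFrame, spec: ModelSpec) -> VarComponents:
    """REML variance components under ``spec``.

    Handles missing animal-day cells and arbitrary covariates.  Starting
    values come from the balanced ANOVA solution when the layout permits.
    """
    df = _gas_frame(flux, spec.gas)
    y = df["flux_lph"].to_numpy(float)
    X, names, factors = _design(df, spec)

    start = None
    if not spec.fixed and set(spec.random) == {"animal", "day"}:
        try:
            vc0 = fit_anova_balanced(df, spec.gas)
            floor = max(1e-4 * np.var(y), 1e-30)
            start = np.array([
                max(vc0.sigma2_animal, floor),
                max(vc0.sigma2_day, floor),
                max(vc0.sigma2_error, floor),
            ])
        except ValueError:
            pass

    res = reml_fit(y, X, factors, beta_names=names, start=start)
    if not res.converged:
        raise RuntimeError(
            f"REML did not converge for gas {spec.gas!r} "
            f"after {res.n_iter} iterations"
        )
    v = res.all_variances
    vc = VarComponents(
        gas=spec.gas, estimator="reml",
        sigma2_animal=v.get("animal", 0.0),
        sigma2_day=v.get("day", 0.0),
        sigma2_error=v["error"],
        se_animal=res.se.get("animal", float("nan")),
        se_day=res.se.get("day", float("nan")),
        se_error=res.se["error"],
        mean_lph=float(y.mean()),
        loglik=res.loglik,
        fixed_effects=tuple(names[1:]),
        truncated=res.truncated,
        converged=res.converged,
    )
    return derive_summaries(vc)


def derive_summaries(
    vc: VarComponents, *, repeatability_denominator: str = "animal_error"
) -> VarComponents:
    """Fill H_ani, CV and repeatability from the fitted components.

    ``repeatability_denominator``: ``"animal_error"`` (default) uses
    sigma2_animal / (sigma2_animal + sigma2_error); ``"total"`` also adds
    the day variance to the denominator.
    """
    if repeatability_denominator not in ("animal_error", "total"):
        raise ValueError("repeatability_denominator must be 'animal_error' or 'total'")
    tot = vc.total_variance
    h = vc.sigma2_animal / tot if tot > 0 else 0.0
    if vc.sigma2_animal == 0:
        cv = 0.0
    else:
        if vc.mean_lph == 0:
            raise ValueError("CV undefined: trait mean is zero")
        cv = float(np.sqrt(vc.sigma2_animal) / vc.mean_lph)
    denom = vc.sigma2_animal + vc.sigma2_error
    if repeatability_denominator == "total":
        denom += vc.sigma2_day
    rep = vc.sigma2_animal / denom if denom > 0 else 0.0
    return replace(vc, h_animal=h, cv=cv, repeatability=rep)


def repeatability_spec(gas: str) -> ModelSpec:
    """The study's repeatability model for ``gas``."""
    return ModelSpec(gas=gas, fixed=REPEATABILITY_SPEC_FIXED)


def repeatability_by_window(
    flux: pd.DataFrame, gas: str, n: int, spec: ModelSpec | None = None
) -> float:
    """Repeatability from the first ``n`` consecutive measurement days."""
    df = _gas_frame(flux, gas)
    days = np.sort(df["day_index"].unique())
    if not (2 <= n <= len(days)):
        raise ValueError(f"window n={n} outside [2, {len(days)}]")
    sub = df[df["day_index"].isin(days[:n])]
    vc = fit_reml(sub, spec or repeatability_spec(gas))
    return float(vc.repeatability)


def repeatability_curve(
    flux: pd.DataFrame, gas: str, spec: ModelSpec | None = None
) -> pd.DataFrame:
    """Windowed repeatability for every prefix of consecutive days."""
    days = np.sort(_gas_frame(flux, gas)["day_index"].unique())
    rows = [
        {"gas": check_gas(gas), "n_days": n,
         "repeatability": repeatability_by_window(flux, gas, n, spec)}
        for n in range(2, len(days) + 1)
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    pvalue: float
    df_dropped: int
    loglik_full: float
    loglik_reduced: float


def lrt_nested(
    flux: pd.DataFrame, full: ModelSpec, reduced: ModelSpec
) -> LRTResult:
    """Likelihood-ratio test for dropping random effects.

    Both models must share the response and fixed effects, with the
    reduced model's random effects a subset of the full model's.  Because
    the null value of a variance sits on the parameter-space boundary, the
    p-value uses the 50:50 chi-square mixture (chi2_0 / chi2_1 when one
    component is dropped, chi2_{m-1} / chi2_m for m > 1).
    """
    if full.gas != reduced.gas or full.fixed != reduced.fixed:
        raise ValueError("models must share response gas and fixed effects")
    if not set(reduced.random) <= set(full.random):
        raise ValueError("reduced model's random effects are not nested in full's")
    m = len(set(full.random) - set(reduced.random))
    ll_full = fit_reml(flux, full).loglik
    ll_red = fit_reml(flux, reduced).loglik
    stat = max(2.0 * (ll_full - ll_red), 0.0)
    if m == 0 or stat == 0.0:
        p = 1.0
    elif m == 1:
        p = 0.5 * stats.chi2.sf(stat, 1)
    else:
        p = 0.5 * stats.chi2.sf(stat, m - 1) + 0.5 * stats.chi2.sf(stat, m)
    return LRTResult(stat, float(p), m, ll_full, ll_red)


def varcomp_report(vcs: list[VarComponents]) -> pd.DataFrame:
    """Tabular report (one row per fitted gas/estimator)."""
    rows = []
    for vc in vcs:
        rows.append({
            "gas": vc.gas, "estimator": vc.estimator,
            "mean_lph": vc.mean_lph,
            "sigma2_animal": vc.sigma2_animal, "se_animal": vc.se_animal,
            "sigma2_day": vc.sigma2_day, "se_day": vc.se_day,
            "sigma2_error": vc.sigma2_error, "se_error": vc.se_error,
            "h_animal_pct": 100.0 * (vc.h_animal or 0.0),
            "day_share_pct": 100.0 * vc.day_share,
            "cv": vc.cv, "repeatability": vc.repeatability,
            "loglik": vc.loglik,
            "truncated": ";".join(vc.truncated),
        })
    return pd.DataFrame(rows)
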