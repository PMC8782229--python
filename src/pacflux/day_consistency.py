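"""Persistence of animal rankings across measurement days.

If animals truly differ in emission level, their fluxes on any two days
should correlate: the expected Pearson correlation between two days
equals the intraclass correlation sigma2_animal / (sigma2_animal +
sigma2_error) (the day effect shifts all animals equally and cancels from
a within-day correlation).  This module computes the full day-by-day
correlation / regression structure and tail-membership counts (how often
each animal ranks among the k lowest or k highest emitters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import check_gas


@dataclass
class DayMatrix:
    """Day-pair association structure for one gas.

    All matrices are (n_days x n_days) DataFrames indexed by day.  Slopes
    regress the column day's flux on the row day's flux.  Pairs that are
    undefined (a zero-variance day, or < 2 complete animal pairs) are NaN,
    with the reason recorded in ``missing_reasons``.
    """

    gas: str
    correlation: pd.DataFrame
    slope: pd.DataFrame
    slope_se: pd.DataFrame
    r2: pd.DataFrame
    counts: pd.DataFrame
    missing_reasons: dict


def _wide(flux: pd.DataFrame, gas: str) -> pd.DataFrame:
    gas = check_gas(gas)
    df = flux[flux["gas"] == gas] if "gas" in flux.columns else flux
    if df.empty:
        raise ValueError(f"no records for gas {gas!r}")
    return df.pivot_table(
        index="animal_id", columns="day_index", values="flux_lph", aggfunc="mean"
    )


def day_correlation_matrix(
    flux: pd.DataFrame, gas: str, *, method: str = "pearson"
) -> DayMatrix:
    """Pairwise-complete day-by-day correlations, slopes and R^2."""
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    wide = _wide(flux, gas)
    days = wide.columns.to_numpy()
    nd = len(days)
    corr = np.full((nd, nd), np.nan)
    slope = np.full((nd, nd), np.nan)
    slope_se = np.full((nd, nd), np.nan)
    r2 = np.full((nd, nd), np.nan)
    counts = np.zeros((nd, nd), dtype=int)
    reasons: dict = {}
    for i in range(nd):
        xi = wide.iloc[:, i]
        for j in range(nd):
            yj = wide.iloc[:, j]
            ok = xi.notna() & yj.notna()
            counts[i, j] = int(ok.sum())
            if counts[i, j] < 2:
                reasons[(days[i], days[j])] = "fewer than 2 complete pairs"
                continue
            x, y = xi[ok].to_numpy(), yj[ok].to_numpy()
            if np.var(x) == 0 or np.var(y) == 0:
                reasons[(days[i], days[j])] = "zero variance on one day"
                continue
            if method == "spearman":
                x, y = stats.rankdata(x), stats.rankdata(y)
            res = stats.linregress(x, y)
            corr[i, j] = res.rvalue
            slope[i, j] = res.slope
            slope_se[i, j] = res.stderr
            r2[i, j] = res.rvalue**2
    idx = pd.Index(days, name="day_index")
    return DayMatrix(
        gas=check_gas(gas),
        correlation=pd.DataFrame(corr, index=idx, columns=idx),
        slope=pd.DataFrame(slope, index=idx, columns=idx),
        slope_se=pd.DataFrame(slope_se, index=idx, columns=idx),
        r2=pd.DataFrame(r2, index=idx, columns=idx),
        counts=pd.DataFrame(counts, index=idx, columns=idx),
        missing_reasons=reasons,
    )


@dataclass
class RankingSummary:
    """Tail-membership counts per animal across days.

    ``summary`` has one row per animal: days (and fraction of days) spent
    in the bottom-k (lowest emitters) and top-k tails.  ``ranks`` holds the
    per-day ascending rank of every animal.  Fractions are also given
    rounded to the nearest integer percent.
    """

    gas: str
    k: int
    n_days: int
    summary: pd.DataFrame
    ranks: pd.DataFrame
    boundary_ties: list


def ranking_consistency(flux: pd.DataFrame, gas: str, k: int = 10) -> RankingSummary:
    """Accumulate bottom-k / top-k membership per animal across days.

    Animals are ranked ascending by flux within each day; ties are broken
    by animal id (stable), and any tie crossing the k-th boundary is
    recorded in ``boundary_ties``.
    """
    wide = _wide(flux, gas)
    n_animals = wide.shape[0]
    if not (0 < k < n_animals):
        raise ValueError(f"k={k} must be in (0, n_animals={n_animals})")
    days = wide.columns.tolist()
    bottom = pd.Series(0, index=wide.index)
    top = pd.Series(0, index=wide.index)
    ranks = {}
    ties = []
    for day in days:
        col = wide[day].dropna()
        if len(col) < k:
            raise ValueError(f"day {day} has only {len(col)} valid fluxes (< k={k})")
        order = col.rename("flux").reset_index().sort_values(
            ["flux", "animal_id"], kind="stable"
        )["animal_id"].tolist()
        vals = col.loc[order].to_numpy()
        if vals[k - 1] == vals[k]:
            ties.append((day, "bottom", float(vals[k - 1])))
        if vals[-k] == vals[-k - 1]:
            ties.append((day, "top", float(vals[-k])))
        bottom.loc[order[:k]] += 1
        top.loc[order[-k:]] += 1
        ranks[day] = pd.Series(np.arange(1, len(order) + 1), index=order)
    n_days = len(days)
    summary = pd.DataFrame({
        "animal_id": wide.index,
        "days_in_bottom_k": bottom.to_numpy(),
        "days_in_top_k": top.to_numpy(),
    })
    summary["frac_bottom_k"] = summary["days_in_bottom_k"] / n_days
    summary["frac_top_k"] = summary["days_in_top_k"] / n_days
    summary["pct_bottom_k"] = (100 * summary["frac_bottom_k"]).round().astype(int)
    summary["pct_top_k"] = (100 * summary["frac_top_k"]).round().astype(int)
    rank_table = pd.DataFrame(ranks)
    rank_table.columns.name = "day_index"
    return RankingSummary(
        gas=check_gas(gas), k=k, n_days=n_days,
        summary=summary.reset_index(drop=True),
        ranks=rank_table, boundary_ties=ties,
    )
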