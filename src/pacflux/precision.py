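"""Measurement-precision design curves.

Averaging a trait over n days shrinks the error contribution by 1/n, so
the 95% confidence-interval range of the n-day average is

    P_n = 1.96 * sqrt(sigma2_error / n)

P_n is strictly decreasing in n and obeys the inverse-square law
P_{4n} = P_n / 2: quadrupling the days halves the interval.  Both the full
range P_n and the half-range P_n/2 (the "plus-minus" read) are reported;
published precision figures use either convention, so neither is silently
chosen (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

Z_95 = 1.96  # two-sided 95% normal quantile, as conventionally rounded


@dataclass(frozen=True)
class PrecisionCurve:
    gas: str | None
    sigma2_error: float
    table: pd.DataFrame  # columns: n, p_n, half_range


def precision_value(sigma2_error: float, n: int | np.ndarray) -> float | np.ndarray:
    """P_n for a single n (or vector of n)."""
    if sigma2_error < 0:
        raise ValueError("error variance must be non-negative")
    return Z_95 * np.sqrt(sigma2_error / np.asarray(n, float))


def precision_curve(
    sigma2_error: float, n_max: int = 17, gas: str | None = None
) -> PrecisionCurve:
    """P_n and its half-range for n = 1..n_max."""
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    n = np.arange(1, n_max + 1)
    p = precision_value(sigma2_error, n)
    table = pd.DataFrame({"n": n, "p_n": p, "half_range": p / 2.0})
    if gas is not None:
        table.insert(0, "gas", gas)
    return PrecisionCurve(gas=gas, sigma2_error=sigma2_error, table=table)


def days_for_precision(sigma2_error: float, target: float) -> int:
    """Smallest n with P_n <= target: ceil(1.96^2 * sigma2_e / target^2)."""
    if target <= 0:
        raise ValueError("target precision must be positive")
    if sigma2_error < 0:
        raise ValueError("error variance must be non-negative")
    if sigma2_error == 0:
        return 1
    x = Z_95**2 * sigma2_error / target**2
    # guard against 1-ulp overshoot at exact-hit targets
    n = math.ceil(x - 1e-9 * x)
    return max(n, 1)
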