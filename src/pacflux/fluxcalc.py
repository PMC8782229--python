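"""Chamber gas traces -> volumetric flux (l/h) -> daily mass output (g/d).

A portable accumulation chamber (PAC) run yields three concentration
readings per gas over ~50 minutes.  The flux in liters per hour follows
from the two-point concentration change, the free headspace of the chamber
(chamber volume minus animal liveweight, the printed formula treating kg of
animal as liters displaced), and the concentration scale of the gas:

    flux = (C_x - C_y) / (T_x - T_y) * 60 * (V - liveweight) / D

with ``D = 1e6`` for ppm-scale CH4 and ``D = 100`` for percent-scale O2 and
CO2.  For the produced gases (CH4, CO2) ``x`` is the last reading and ``y``
the first; for consumed O2 the order is reversed, so a normally breathing
animal yields positive values for all three gases.

The daily mass extrapolation applies the ideal-gas molar density at the
ambient temperature and pressure of the run:

    g/d = flux * (P_hPa * 0.1) / (8.3145 * (T_C + 273.15)) * M * 1440

evaluated exactly in this form (see docs/methods.md for a note on the
units of the 1440 factor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import (
    CHAMBER_VOLUME_L,
    CONSUMED_GASES,
    GASES,
    HPA_TO_KPA,
    KELVIN_OFFSET,
    MINUTES_PER_DAY,
    MOLAR_MASS,
    R_GAS,
    SCALE_DIVISOR,
    check_gas,
)

logger = logging.getLogger(__name__)

#: Default tolerance for the mid-reading linearity QC check, as a fraction
#: of the first-to-last concentration change.
LINEARITY_TOL = 0.10


@dataclass(frozen=True)
class GasTrace:
    """One animal-run's readings for a single gas.

    ``readings`` are in ppm for CH4 and percent for O2/CO2; ``times_min``
    are minutes after chamber entry (nominally 0, 25, 50).
    """

    gas: str
    readings: tuple[float, float, float]
    times_min: tuple[float, float, float]
    liveweight_kg: float
    chamber_volume_l: float = CHAMBER_VOLUME_L

    def __post_init__(self) -> None:
        object.__setattr__(self, "gas", check_gas(self.gas))
        t = self.times_min
        if not (t[0] < t[1] < t[2]):
            raise ValueError(f"times must be strictly increasing, got {t}")
        lo, hi = (0.0, np.inf) if self.gas == "ch4" else (0.0, 100.0)
        for c in self.readings:
            if not (lo <= c <= hi):
                raise ValueError(
                    f"{self.gas} reading {c} outside physical range [{lo}, {hi}]"
                )
        if self.liveweight_kg >= self.chamber_volume_l:
            raise ValueError(
                "liveweight exceeds chamber volume: net headspace non-positive"
            )


@dataclass(frozen=True)
class FluxRecord:
    """A derived per-gas flux for one animal-day.

    Sign convention: production positive for CH4/CO2, consumption positive
    for O2.  Negative values are physiologically anomalous but preserved
    (and flagged), never clamped.
    """

    animal_id: str
    day_index: int
    gas: str
    flux_lph: float
    flux_gpd: float | None = None
    qc_flags: tuple[str, ...] = field(default_factory=tuple)


def trace_to_flux_lph(trace: GasTrace, *, linearity_tol: float = LINEARITY_TOL):
    """Convert a three-point trace to a flux in l/h.

    Returns ``(flux, qc_flags)``.  The slope uses the first and last
    readings at their actual recorded times; the middle reading only feeds
    a linearity QC flag (``nonlinear_trace``) when it deviates from the
    chord midpoint by more than ``linearity_tol`` times the total change.
    A negative flux is flagged ``negative_flux``.
    """
    c0, c1, c2 = trace.readings
    t0, _, t2 = trace.times_min
    if t2 == t0:  # unreachable given the invariant, kept for raw callers
        raise ZeroDivisionError("zero time difference between first and last reading")
    if trace.gas in CONSUMED_GASES:
        delta = c0 - c2
    else:
        delta = c2 - c0
    net_volume = trace.chamber_volume_l - trace.liveweight_kg
    flux = delta / (t2 - t0) * 60.0 * net_volume / SCALE_DIVISOR[trace.gas]

    flags: list[str] = []
    chord_mid = c0 + (c2 - c0) * (trace.times_min[1] - t0) / (t2 - t0)
    total_change = abs(c2 - c0)
    if total_change > 0 and abs(c1 - chord_mid) > linearity_tol * total_change:
        flags.append("nonlinear_trace")
    if flux < 0:
        flags.append("negative_flux")
    return flux, tuple(flags)


def flux_lph_to_gpd(
    flux_lph: float, temperature_c: float, pressure_hpa: float, gas: str
) -> float:
    """Extrapolate a volumetric flux to a daily mass output in g/d."""
    gas = check_gas(gas)
    if temperature_c <= -KELVIN_OFFSET:
        raise ValueError("temperature at or below absolute zero")
    if pressure_hpa <= 0:
        raise ValueError("pressure must be positive")
    molar_density = (pressure_hpa * HPA_TO_KPA) / (
        R_GAS * (temperature_c + KELVIN_OFFSET)
    )
    return flux_lph * molar_density * MOLAR_MASS[gas] * MINUTES_PER_DAY


# Trial-table column layout for the per-gas readings.
_GAS_COLUMNS = {
    "ch4": ("ch4_ppm_t0", "ch4_ppm_t1", "ch4_ppm_t2"),
    "o2": ("o2_pct_t0", "o2_pct_t1", "o2_pct_t2"),
    "co2": ("co2_pct_t0", "co2_pct_t1", "co2_pct_t2"),
}

#: Covariates carried from the trial table into the flux table so the
#: variance, repeatability and prediction models can run off the flux
#: table alone.
_CARRY_COLUMNS = (
    "run_index",
    "chamber_id",
    "breed",
    "age_months",
    "liveweight_kg",
    "temp_c",
    "pressure_hpa",
    "humidity_pct",
)

FLUX_COLUMNS = (
    ("animal_id", "day_index", "gas", "flux_lph", "flux_gpd", "qc_flags")
    + _CARRY_COLUMNS
)


def flux_table(
    trial: pd.DataFrame,
    *,
    gases: Sequence[str] = GASES,
    chamber_volume_l: float = CHAMBER_VOLUME_L,
    linearity_tol: float = LINEARITY_TOL,
) -> pd.DataFrame:
    """Convert a long-format trial table to a flux table.

    One output row per animal x day x gas.  Rows whose trace violates the
    trace invariants are excluded and logged with the reason; valid rows
    with anomalies (negative flux, nonlinear trace) are kept and flagged
    in ``qc_flags`` (semicolon-joined, empty when clean).
    """
    if trial.empty:
        raise ValueError("empty trial table")
    gases = [check_gas(g) for g in gases]

    out: list[dict] = []
    n_excluded = 0
    for row in trial.itertuples(index=False):
        times = (row.t0_min, row.t1_min, row.t2_min)
        for gas in gases:
            c0n, c1n, c2n = _GAS_COLUMNS[gas]
            readings = (getattr(row, c0n), getattr(row, c1n), getattr(row, c2n))
            try:
                trace = GasTrace(
                    gas=gas,
                    readings=readings,
                    times_min=times,
                    liveweight_kg=row.liveweight_kg,
                    chamber_volume_l=chamber_volume_l,
                )
            except (ValueError, TypeError) as exc:
                n_excluded += 1
                logger.warning(
                    "excluding animal %s day %s gas %s: %s",
                    row.animal_id, row.day_index, gas, exc,
                )
                continue
            flux, flags = trace_to_flux_lph(trace, linearity_tol=linearity_tol)
            gpd = flux_lph_to_gpd(flux, row.temp_c, row.pressure_hpa, gas)
            rec = {
                "animal_id": row.animal_id,
                "day_index": row.day_index,
                "gas": gas,
                "flux_lph": flux,
                "flux_gpd": gpd,
                "qc_flags": ";".join(flags),
            }
            for col in _CARRY_COLUMNS:
                rec[col] = getattr(row, col, np.nan)
            out.append(rec)
    if not out:
        raise ValueError("no valid records remained after validation")
    if n_excluded:
        logger.warning("excluded %d invalid gas traces", n_excluded)
    return pd.DataFrame(out, columns=list(FLUX_COLUMNS))
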