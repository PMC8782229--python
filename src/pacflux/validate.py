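"""Input validation for trial tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .synthetic import TRIAL_COLUMNS

# plausibility windows for ambient conditions
_ENV_RANGES = {
    "temp_c": (-30.0, 50.0),
    "pressure_hpa": (800.0, 1100.0),
    "humidity_pct": (0.0, 100.0),
}


@dataclass
class ValidationReport:
    n_rows: int
    n_passed: int
    failures: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def ok(self) -> bool:
        return self.n_passed == self.n_rows


def validate_input(trial: pd.DataFrame, chamber_volume_l: float = 853.0) -> ValidationReport:
    """Row-level checks of a trial table.

    Flags non-increasing reading times, out-of-range concentrations,
    non-positive net chamber volume, implausible ambient conditions and
    duplicated animal-day rows.  Returns pass/fail counts with reasons.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trial.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    fails: list[dict] = []

    def flag(idx, row, reason):
        fails.append({
            "row": idx, "animal_id": row.animal_id,
            "day_index": row.day_index, "reason": reason,
        })

    dup = trial.duplicated(subset=["animal_id", "day_index"], keep=False)
    for idx, row in enumerate(trial.itertuples(index=False)):
        if dup.iloc[idx]:
            flag(idx, row, "duplicate animal-day")
        if not (row.t0_min < row.t1_min < row.t2_min):
            flag(idx, row, "reading times not strictly increasing")
        if row.liveweight_kg >= chamber_volume_l:
            flag(idx, row, "net volume non-positive")
        for col in ("ch4_ppm_t0", "ch4_ppm_t1", "ch4_ppm_t2"):
            if getattr(row, col) < 0:
                flag(idx, row, f"{col} negative")
        for col in ("o2_pct_t0", "o2_pct_t1", "o2_pct_t2",
                    "co2_pct_t0", "co2_pct_t1", "co2_pct_t2"):
            if not (0.0 <= getattr(row, col) <= 100.0):
                flag(idx, row, f"{col} outside [0, 100]")
        for col, (lo, hi) in _ENV_RANGES.items():
            if not (lo <= getattr(row, col) <= hi):
                flag(idx, row, f"{col} outside [{lo}, {hi}]")

    failures = pd.DataFrame(fails, columns=["row", "animal_id", "day_index", "reason"])
    n_failed_rows = failures["row"].nunique() if not failures.empty else 0
    return ValidationReport(
        n_rows=len(trial), n_passed=len(trial) - n_failed_rows, failures=failures
    )
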