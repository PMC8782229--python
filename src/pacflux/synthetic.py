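"""Synthetic PAC trial generator.

Emulates the measurement design of the motivating study: 48 ewe lambs
measured on 17 consecutive days, four runs of 12 chambers per day, three
gas readings per run.  Each gas flux follows the additive model

    y_ij = mu + a_i + d_j + e_ij,   a ~ N(0, s2_animal),
                                    d ~ N(0, s2_day),
                                    e ~ N(0, s2_error),

independently per gas.  Default means and variance components are the
study's reported values for CH4, O2 and CO2.  Traces are constructed by
inverting the flux equations (linear accumulation between the first and
last readings), so feeding a generated trial back through
:mod:`pacflux.fluxcalc` recovers the generating fluxes to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import CHAMBER_VOLUME_L, CONSUMED_GASES, GASES, SCALE_DIVISOR, check_gas

TRIAL_COLUMNS = (
    "animal_id", "breed", "age_months", "day_index", "run_index", "chamber_id",
    "liveweight_kg", "t0_min", "t1_min", "t2_min",
    "ch4_ppm_t0", "ch4_ppm_t1", "ch4_ppm_t2",
    "o2_pct_t0", "o2_pct_t1", "o2_pct_t2",
    "co2_pct_t0", "co2_pct_t1", "co2_pct_t2",
    "temp_c", "pressure_hpa", "humidity_pct",
)

TRUTH_COLUMNS = (
    "animal_id", "day_index", "gas",
    "animal_effect", "day_effect", "residual", "true_flux_lph",
)


@dataclass(frozen=True)
class TrialDesign:
    """Layout of a PAC trial."""

    n_animals: int = 48
    n_days: int = 17
    n_runs_per_day: int = 4
    n_chambers: int = 12
    chamber_volume_l: float = CHAMBER_VOLUME_L
    reading_times_min: tuple[float, float, float] = (0.0, 25.0, 50.0)

    def __post_init__(self) -> None:
        if min(self.n_animals, self.n_days, self.n_runs_per_day, self.n_chambers) < 1:
            raise ValueError("all design counts must be >= 1")
        t = self.reading_times_min
        if not (t[0] < t[1] < t[2]):
            raise ValueError("reading times must be strictly increasing")
        if self.n_animals > self.n_runs_per_day * self.n_chambers:
            raise ValueError(
                "n_animals exceeds daily chamber capacity "
                f"({self.n_runs_per_day} runs x {self.n_chambers} chambers)"
            )


@dataclass(frozen=True)
class GasParams:
    """Mean flux, variance components and ambient baseline for one gas.

    ``baseline`` is the fresh-air concentration at chamber sealing, in the
    gas's native units (ppm for CH4, percent for O2/CO2).  Only
    concentration *differences* enter the flux equations, so the baseline
    does not affect downstream statistics.
    """

    mean_lph: float
    var_animal: float
    var_day: float
    var_error: float
    baseline: float

    def __post_init__(self) -> None:
        if min(self.var_animal, self.var_day, self.var_error) < 0:
            raise ValueError("variance components must be non-negative")
        if self.baseline < 0:
            raise ValueError("baseline concentration must be non-negative")


#: Study-reported per-gas means and variance components ((l/h) and (l/h)^2),
#: with typical ambient-air baselines.
DEFAULT_GAS_PARAMS = {
    "ch4": GasParams(0.0094, 0.0000018, 0.0000030, 0.0000077, baseline=2.0),
    "o2": GasParams(0.3582, 0.0056, 0.0069, 0.0051, baseline=20.9),
    "co2": GasParams(0.2194, 0.0014, 0.0023, 0.0021, baseline=0.04),
}


@dataclass(frozen=True)
class SimParams:
    """All stochastic inputs of the generator.

    Environment means/SDs are the study's reported trial-period averages.
    ``reading_noise`` adds i.i.d. Gaussian noise (native units) to every
    stored reading; ``time_jitter_min`` perturbs the recorded second and
    third reading times uniformly within +/- that many minutes.  Both
    default to 0, making the trace construction exactly invertible.
    """

    gases: dict = field(default_factory=lambda: dict(DEFAULT_GAS_PARAMS))
    liveweight_mean: float = 46.0
    liveweight_sd: float = 4.0
    temp_mean: float = 8.33
    temp_sd: float = 2.45
    pressure_mean: float = 1000.05
    pressure_sd: float = 15.79
    humidity_mean: float = 76.68
    humidity_sd: float = 8.66
    breeds: tuple[str, ...] = ("Texel", "Suffolk")
    age_months_range: tuple[int, int] = (10, 11)
    reading_noise: float = 0.0
    time_jitter_min: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for gas in self.gases:
            check_gas(gas)
        o2 = self.gases.get("o2")
        if o2 is not None and o2.baseline > 20.95:
            raise ValueError("O2 baseline above the atmospheric fraction (20.95%)")


@dataclass
class SyntheticTrial:
    """A complete generated trial: animal roster, per-run environment,
    the long-format trace table, and the generating truth table."""

    design: TrialDesign
    params: SimParams
    animals: pd.DataFrame
    environment: pd.DataFrame
    trial: pd.DataFrame
    truth: pd.DataFrame


def _spawn(rng_seed: int, key: int) -> np.random.Generator:
    """Independent stream for one generator component."""
    return np.random.default_rng(np.random.SeedSequence(rng_seed).spawn(key + 1)[key])


def simulate_flux_effects(
    params: SimParams,
    design: TrialDesign,
    rng: np.random.Generator | None = None,
    gases=None,
) -> pd.DataFrame:
    """Draw animal/day/residual effects and compose true fluxes per gas.

    This is the truth table of :func:`simulate_trial`, exposed separately
    because variance-component recovery studies need only the fluxes.
    """
    if rng is None:
        rng = _spawn(params.seed, 0)
    gases = list(params.gases) if gases is None else [check_gas(g) for g in gases]
    na, nd = design.n_animals, design.n_days
    animal_ids = [f"A{i + 1:03d}" for i in range(na)]
    rows = []
    for gas in gases:
        gp = params.gases[gas]
        a = rng.normal(0.0, np.sqrt(gp.var_animal), na)
        d = rng.normal(0.0, np.sqrt(gp.var_day), nd)
        e = rng.normal(0.0, np.sqrt(gp.var_error), (na, nd))
        for i in range(na):
            for j in range(nd):
                rows.append(
                    (animal_ids[i], j + 1, gas, a[i], d[j], e[i, j],
                     gp.mean_lph + a[i] + d[j] + e[i, j])
                )
    return pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))


def _trace_from_flux(
    flux: float, gas: str, baseline: float, liveweight: float,
    times: tuple[float, float, float], chamber_volume: float,
) -> tuple[float, float, float]:
    """Invert the two-point flux equation: linear accumulation readings."""
    span_h = (times[2] - times[0]) / 60.0
    delta = flux * SCALE_DIVISOR[gas] * span_h / (chamber_volume - liveweight)
    if gas in CONSUMED_GASES:
        delta = -delta
    c0 = baseline
    c2 = baseline + delta
    frac = (times[1] - times[0]) / (times[2] - times[0])
    c1 = c0 + frac * delta
    return c0, c1, c2


def simulate_trial(
    params: SimParams,
    design: TrialDesign | None = None,
    *,
    on_invalid: str = "raise",
) -> SyntheticTrial:
    """Generate a full synthetic PAC trial.

    Records whose implied chamber reading would be negative (a flux /
    baseline combination with no physical trace) are rejected: ``raise``
    (default) aborts with a diagnostic naming the record, ``drop``
    excludes the animal-day row from the trace table (the truth table
    keeps it, so dropped cells look like missed measurements downstream).
    """
    if design is None:
        design = TrialDesign()
    if on_invalid not in ("raise", "drop"):
        raise ValueError("on_invalid must be 'raise' or 'drop'")

    rng_truth = _spawn(params.seed, 0)
    rng_roster = _spawn(params.seed, 1)
    rng_env = _spawn(params.seed, 2)
    rng_assign = _spawn(params.seed, 3)
    rng_noise = _spawn(params.seed, 4)

    na, nd = design.n_animals, design.n_days
    truth = simulate_flux_effects(params, design, rng_truth)
    flux_of = {
        (r.animal_id, r.day_index, r.gas): r.true_flux_lph
        for r in truth.itertuples(index=False)
    }

    animal_ids = [f"A{i + 1:03d}" for i in range(na)]
    lo, hi = params.age_months_range
    animals = pd.DataFrame(
        {
            "animal_id": animal_ids,
            "breed": rng_roster.choice(params.breeds, na),
            "age_months": rng_roster.integers(lo, hi + 1, na),
            "liveweight_kg": rng_roster.normal(
                params.liveweight_mean, params.liveweight_sd, na
            ),
        }
    )
    if (animals["liveweight_kg"] >= design.chamber_volume_l).any():
        raise ValueError("drawn liveweight exceeds chamber volume")

    env_rows = []
    for j in range(1, nd + 1):
        for r in range(1, design.n_runs_per_day + 1):
            env_rows.append(
                (j, r,
                 rng_env.normal(params.temp_mean, params.temp_sd),
                 rng_env.normal(params.pressure_mean, params.pressure_sd),
                 rng_env.normal(params.humidity_mean, params.humidity_sd))
            )
    environment = pd.DataFrame(
        env_rows, columns=["day_index", "run_index", "temp_c", "pressure_hpa",
                           "humidity_pct"],
    )
    env_of = {
        (r.day_index, r.run_index): (r.temp_c, r.pressure_hpa, r.humidity_pct)
        for r in environment.itertuples(index=False)
    }

    t_nominal = design.reading_times_min
    gas_order = list(params.gases)
    trial_rows = []
    for j in range(1, nd + 1):
        order = rng_assign.permutation(na)
        for pos, ai in enumerate(order):
            run = pos // design.n_chambers + 1
            chamber = pos % design.n_chambers + 1
            arow = animals.iloc[ai]
            temp, press, hum = env_of[(j, run)]
            times = t_nominal
            if params.time_jitter_min > 0:
                j1, j2 = rng_noise.uniform(
                    -params.time_jitter_min, params.time_jitter_min, 2
                )
                times = (t_nominal[0], t_nominal[1] + j1, t_nominal[2] + j2)
            rec = {
                "animal_id": arow.animal_id,
                "breed": arow.breed,
                "age_months": int(arow.age_months),
                "day_index": j,
                "run_index": run,
                "chamber_id": chamber,
                "liveweight_kg": arow.liveweight_kg,
                "t0_min": times[0], "t1_min": times[1], "t2_min": times[2],
                "temp_c": temp, "pressure_hpa": press, "humidity_pct": hum,
            }
            bad = None
            for gas in gas_order:
                gp = params.gases[gas]
                flux = flux_of[(arow.animal_id, j, gas)]
                c0, c1, c2 = _trace_from_flux(
                    flux, gas, gp.baseline, arow.liveweight_kg, times,
                    design.chamber_volume_l,
                )
                if params.reading_noise > 0:
                    c0, c1, c2 = (
                        c + rng_noise.normal(0.0, params.reading_noise)
                        for c in (c0, c1, c2)
                    )
                if min(c0, c1, c2) < 0:
                    bad = (
                        f"animal {arow.animal_id} day {j} gas {gas}: flux "
                        f"{flux:.6g} l/h with baseline {gp.baseline} implies a "
                        "negative chamber reading"
                    )
                    break
                unit = "ppm" if gas == "ch4" else "pct"
                rec[f"{gas}_{unit}_t0"] = c0
                rec[f"{gas}_{unit}_t1"] = c1
                rec[f"{gas}_{unit}_t2"] = c2
            if bad is not None:
                if on_invalid == "raise":
                    raise ValueError(bad)
                continue
            trial_rows.append(rec)

    trial = pd.DataFrame(trial_rows, columns=list(TRIAL_COLUMNS))
    return SyntheticTrial(
        design=design, params=params, animals=animals,
        environment=environment, trial=trial, truth=truth,
    )


def write_trial(
    trial: SyntheticTrial, path: str | Path, *, include_truth: bool = True
) -> dict[str, Path]:
    """Write a generated trial to ``<path>/trial.csv`` (+ ``truth.csv``).

    Omitting the truth output still yields a complete analysis input set;
    the truth CSV exists only for parameter-recovery work.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = {"trial": path / "trial.csv"}
    trial.trial.to_csv(files["trial"], index=False)
    if include_truth:
        files["truth"] = path / "truth.csv"
        trial.truth.to_csv(files["truth"], index=False)
    return files


def read_trial(path: str | Path) -> pd.DataFrame:
    """Read a trial CSV, checking the documented column layout."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV missing columns: {missing}")
    return df[list(TRIAL_COLUMNS)]
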