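import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pacflux import SimParams, TrialDesign, flux_table, simulate_trial
from pacflux.synthetic import simulate_flux_effects

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: Study-reported variance triples (animal, day, error), (l/h)^2.
TABLE_VARIANCES = {
    "ch4": (0.0000018, 0.0000030, 0.0000077),
    "o2": (0.0056, 0.0069, 0.0051),
    "co2": (0.0014, 0.0023, 0.0021),
}
TABLE_MEANS = {"ch4": 0.0094, "o2": 0.3582, "co2": 0.2194}


@pytest.fixture(scope="session")
def default_trial():
    """One full-size synthetic trial (48 animals x 17 days)."""
    return simulate_trial(SimParams(seed=0))


@pytest.fixture(scope="session")
def default_flux(default_trial):
    return flux_table(default_trial.trial)


@pytest.fixture(scope="session")
def small_design():
    return TrialDesign(n_animals=8, n_days=5, n_runs_per_day=2, n_chambers=4)


def flux_frame(rng, gas="o2", n_animals=48, n_days=17, params=None):
    """Flux-level simulation shortcut used by the Monte-Carlo suites."""
    design = TrialDesign() if (n_animals, n_days) == (48, 17) else TrialDesign(
        n_animals=n_animals, n_days=n_days,
        n_runs_per_day=4, n_chambers=int(np.ceil(n_animals / 4)),
    )
    params = params or SimParams()
    df = simulate_flux_effects(params, design, rng, gases=[gas])
    return df.rename(columns={"true_flux_lph": "flux_lph"})
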