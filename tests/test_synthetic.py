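import numpy as np
import pandas as pd
import pytest

from pacflux import (
    GasParams,
    SimParams,
    TrialDesign,
    flux_table,
    read_trial,
    simulate_trial,
    write_trial,
)
from pacflux.synthetic import DEFAULT_GAS_PARAMS, simulate_flux_effects


def zero_variance_params(seed=0):
    gases = {
        g: GasParams(p.mean_lph, 0.0, 0.0, 0.0, p.baseline)
        for g, p in DEFAULT_GAS_PARAMS.items()
    }
    return SimParams(gases=gases, seed=seed)


class TestDesignInvariants:
    def test_paper_layout_defaults(self):
        d = TrialDesign()
        assert d.n_animals == d.n_runs_per_day * d.n_chambers == 48
        assert d.n_days == 17 and d.chamber_volume_l == 853

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            TrialDesign(reading_times_min=(0, 50, 25))
        with pytest.raises(ValueError):
            TrialDesign(n_animals=49)  # exceeds 4 runs x 12 chambers

    def test_o2_baseline_capped_at_atmospheric(self):
        gases = dict(DEFAULT_GAS_PARAMS)
        gases["o2"] = GasParams(0.36, 0.005, 0.007, 0.005, baseline=21.5)
        with pytest.raises(ValueError, match="atmospheric"):
            SimParams(gases=gases)


class TestSimulateTrial:
    def test_trace_table_dimensions(self, default_trial):
        assert len(default_trial.trial) == 48 * 17
        assert len(default_trial.truth) == 48 * 17 * 3

    def test_every_animal_once_per_day(self, default_trial):
        per_day = default_trial.trial.groupby("day_index")["animal_id"].nunique()
        assert (per_day == 48).all()

    def test_chamber_assignment_is_permutation_within_run(self, default_trial):
        grp = default_trial.trial.groupby(["day_index", "run_index"])["chamber_id"]
        for _, chambers in grp:
            assert sorted(chambers) == list(range(1, 13))

    def test_determinism_same_seed(self):
        p = SimParams(seed=7)
        a = simulate_trial(p, on_invalid="drop")
        b = simulate_trial(p, on_invalid="drop")
        pd.testing.assert_frame_equal(a.trial, b.trial)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        c = simulate_trial(SimParams(seed=8), on_invalid="drop")
        assert not a.trial.equals(c.trial)

    def test_zero_variances_give_constant_fluxes(self):
        trial = simulate_trial(zero_variance_params(), TrialDesign(
            n_animals=8, n_days=3, n_runs_per_day=2, n_chambers=4))
        for gas, gp in DEFAULT_GAS_PARAMS.items():
            sub = trial.truth[trial.truth["gas"] == gas]
            assert np.allclose(sub["true_flux_lph"], gp.mean_lph, atol=1e-15)

    def test_liveweight_constant_within_trial(self, default_trial):
        per_animal = default_trial.trial.groupby("animal_id")["liveweight_kg"].nunique()
        assert (per_animal == 1).all()

    def test_negative_implied_reading_rejected_with_diagnostic(self):
        gases = dict(DEFAULT_GAS_PARAMS)
        # mean so negative that the CH4 trace cannot exist at 2 ppm ambient
        gases["ch4"] = GasParams(-0.01, 0.0, 0.0, 0.0, baseline=2.0)
        with pytest.raises(ValueError, match="negative chamber reading"):
            simulate_trial(SimParams(gases=gases, seed=0), TrialDesign(
                n_animals=4, n_days=2, n_runs_per_day=1, n_chambers=4))

    def test_time_jitter_keeps_roundtrip_exact(self):
        p = SimParams(seed=11, time_jitter_min=2.0)
        trial = simulate_trial(p, TrialDesign(
            n_animals=8, n_days=4, n_runs_per_day=2, n_chambers=4),
            on_invalid="drop")
        assert (trial.trial["t1_min"] != 25.0).any()
        flux = flux_table(trial.trial)
        merged = flux.merge(trial.truth, on=["animal_id", "day_index", "gas"])
        assert (merged["flux_lph"] - merged["true_flux_lph"]).abs().max() <= 1e-10


class TestStatisticalStructure:
    def test_variance_of_animal_means_matches_total_variance_law(self):
        """Marginal variance of a 17-day animal mean is
        s2_animal + s2_day/17 + s2_error/17."""
        gp = DEFAULT_GAS_PARAMS["o2"]
        expected = gp.var_animal + gp.var_day / 17 + gp.var_error / 17
        rng = np.random.default_rng(123)
        params, design = SimParams(), TrialDesign()
        means = []
        for _ in range(1000):
            df = simulate_flux_effects(params, design, rng, gases=["o2"])
            means.append(
                df.groupby("animal_id")["true_flux_lph"].mean().to_numpy()
            )
        observed = np.concatenate(means).var(ddof=1)
        assert observed == pytest.approx(expected, rel=0.05)

    def test_component_decomposition_recovered_unbiasedly(self):
        """Closed-form component estimates averaged over replicate trials
        match the generating variances (< 5% relative) for each gas."""
        from pacflux.varcomp import fit_anova_balanced

        rng = np.random.default_rng(2024)
        params, design = SimParams(), TrialDesign()
        sums = {g: np.zeros(3) for g in DEFAULT_GAS_PARAMS}
        n_rep = 500
        for _ in range(n_rep):
            df = simulate_flux_effects(params, design, rng).rename(
                columns={"true_flux_lph": "flux_lph"})
            for g in sums:
                vc = fit_anova_balanced(df, g)
                sums[g] += (vc.sigma2_animal, vc.sigma2_day, vc.sigma2_error)
        for g, gp in DEFAULT_GAS_PARAMS.items():
            est = sums[g] / n_rep
            truth = np.array([gp.var_animal, gp.var_day, gp.var_error])
            assert np.all(np.abs(est - truth) / truth < 0.05), (g, est, truth)


class TestWriteRead:
    def test_roundtrip_bit_exact(self, tmp_path, small_design):
        trial = simulate_trial(SimParams(seed=3), small_design, on_invalid="drop")
        files = write_trial(trial, tmp_path)
        back = read_trial(files["trial"])
        pd.testing.assert_frame_equal(back, trial.trial)
        truth = pd.read_csv(files["truth"])
        assert len(truth) == len(trial.truth)

    def test_truth_optional(self, tmp_path, small_design):
        trial = simulate_trial(SimParams(seed=3), small_design, on_invalid="drop")
        files = write_trial(trial, tmp_path, include_truth=False)
        assert "truth" not in files
        flux = flux_table(read_trial(files["trial"]))
        assert not flux.empty
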