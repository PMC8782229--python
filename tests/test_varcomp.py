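import numpy as np
import pandas as pd
import pytest

from conftest import TABLE_MEANS, TABLE_VARIANCES, flux_frame
from pacflux import (
    GasParams,
    ModelSpec,
    SimParams,
    derive_summaries,
    fit_anova_balanced,
    fit_reml,
    lrt_nested,
    repeatability_by_window,
)
from pacflux.varcomp import VarComponents, repeatability_spec


def make_vc(s2a, s2d, s2e, mean=1.0):
    return VarComponents(
        gas="o2", estimator="anova", sigma2_animal=s2a, sigma2_day=s2d,
        sigma2_error=s2e, se_animal=0, se_day=0, se_error=0,
        mean_lph=mean, loglik=float("nan"), fixed_effects=(),
    )


def sim_params(gas, s2a, s2d, s2e, mean=None):
    gp = GasParams(mean if mean is not None else TABLE_MEANS[gas],
                   s2a, s2d, s2e, baseline=20.9)
    return SimParams(gases={gas: gp})


class TestAnovaBalanced:
    def test_constant_data_all_components_zero(self):
        df = pd.DataFrame({
            "animal_id": np.repeat([f"a{i}" for i in range(4)], 3),
            "day_index": np.tile([1, 2, 3], 4),
            "gas": "o2",
            "flux_lph": 0.36,
        })
        vc = fit_anova_balanced(df, "o2")
        for f in ("sigma2_animal", "sigma2_day", "sigma2_error"):
            assert getattr(vc, f) == pytest.approx(0.0, abs=1e-20), f

    def test_two_by_two_hand_computed(self):
        # expected-mean-squares arithmetic: MSA=4, MSD=1, MSE=0
        df = pd.DataFrame({
            "animal_id": ["a1", "a1", "a2", "a2"],
            "day_index": [1, 2, 1, 2],
            "gas": "o2",
            "flux_lph": [1.0, 2.0, 3.0, 4.0],
        })
        vc = fit_anova_balanced(df, "o2")
        assert vc.sigma2_animal == pytest.approx(2.0)
        assert vc.sigma2_day == pytest.approx(0.5)
        assert vc.sigma2_error == pytest.approx(0.0, abs=1e-12)

    def test_unbalanced_input_directs_to_reml(self):
        df = pd.DataFrame({
            "animal_id": ["a1", "a1", "a2"],
            "day_index": [1, 2, 1],
            "gas": "o2",
            "flux_lph": [1.0, 2.0, 3.0],
        })
        with pytest.raises(ValueError, match="fit_reml"):
            fit_anova_balanced(df, "o2")

    def test_negative_estimates_truncated_and_flagged(self):
        rng = np.random.default_rng(5)
        df = flux_frame(rng, "o2", n_animals=4, n_days=4,
                        params=sim_params("o2", 0.0, 0.0, 1.0, mean=5.0))
        vc = fit_anova_balanced(df, "o2")
        assert vc.sigma2_animal >= 0 and vc.sigma2_day >= 0
        if "animal" in vc.truncated or "day" in vc.truncated:
            assert min(vc.sigma2_animal, vc.sigma2_day) == 0.0


class TestREML:
    def test_matches_anova_oracle_on_balanced_interior_data(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            df = flux_frame(rng, "o2", n_animals=12, n_days=8)
            a = fit_anova_balanced(df, "o2")
            if min(a.sigma2_animal, a.sigma2_day, a.sigma2_error) <= 0:
                continue
            r = fit_reml(df, ModelSpec("o2"))
            for f in ("sigma2_animal", "sigma2_day", "sigma2_error"):
                assert getattr(r, f) == pytest.approx(
                    getattr(a, f), rel=1e-6), f

    def test_cross_check_against_statsmodels_mixedlm(self):
        """Independent check: a crossed variance-components fit in
        statsmodels (single-group vc formulation) agrees with ours."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(31)
        df = flux_frame(rng, "o2", n_animals=10, n_days=6)
        ours = fit_reml(df, ModelSpec("o2"))
        df2 = df.assign(g=1)
        md = smf.mixedlm(
            "flux_lph ~ 1", df2, groups="g",
            vc_formula={"animal": "0 + C(animal_id)", "day": "0 + C(day_index)"},
        )
        fit = md.fit(reml=True)
        assert ours.sigma2_animal == pytest.approx(fit.vcomp[0], rel=1e-3)
        assert ours.sigma2_day == pytest.approx(fit.vcomp[1], rel=1e-3)
        assert ours.sigma2_error == pytest.approx(fit.scale, rel=1e-3)

    def test_zero_day_variance_hits_boundary(self):
        rng = np.random.default_rng(3)
        df = flux_frame(rng, "o2", params=sim_params("o2", 0.0056, 0.0, 0.0051))
        vc = fit_reml(df, ModelSpec("o2"))
        assert vc.sigma2_day <= 1e-6
        assert vc.sigma2_animal == pytest.approx(0.0056, rel=0.5)
        assert vc.sigma2_error == pytest.approx(0.0051, rel=0.2)

    def test_missing_cells_recovery(self):
        """Deleting 10% of cells leaves the estimator unbiased."""
        rng = np.random.default_rng(99)
        truth = np.array(TABLE_VARIANCES["o2"])
        est = np.zeros(3)
        n_rep = 200
        for _ in range(n_rep):
            df = flux_frame(rng, "o2")
            keep = rng.random(len(df)) > 0.10
            vc = fit_reml(df[keep], ModelSpec("o2"))
            est += (vc.sigma2_animal, vc.sigma2_day, vc.sigma2_error)
        est /= n_rep
        assert np.all(np.abs(est - truth) / truth < 0.07), est

    def test_fixed_covariates_accepted_and_reported(self, default_flux):
        vc = fit_reml(default_flux, repeatability_spec("o2"))
        assert vc.fixed_effects == ("liveweight_kg", "humidity_pct")
        assert 0 <= vc.repeatability <= 1
        assert np.isfinite(vc.loglik)

    def test_singular_fixed_design_rejected(self, default_flux):
        dup = default_flux.assign(lw2=default_flux["liveweight_kg"])
        with pytest.raises(ValueError, match="singular"):
            fit_reml(dup, ModelSpec("o2", fixed=("liveweight_kg", "lw2")))


class TestDerivedSummaries:
    def test_table_oxygen_row_share(self):
        vc = derive_summaries(make_vc(0.0056, 0.0069, 0.0051, mean=0.3582))
        assert 100 * vc.h_animal == pytest.approx(31.80, abs=0.5)
        assert vc.cv == pytest.approx(np.sqrt(0.0056) / 0.3582)

    def test_day_share_in_published_band(self):
        for s2a, s2d, s2e in (TABLE_VARIANCES["o2"], TABLE_VARIANCES["co2"]):
            vc = derive_summaries(make_vc(s2a, s2d, s2e))
            assert 39.0 <= 100 * vc.day_share <= 40.0

    def test_shares_sum_to_one(self):
        vc = derive_summaries(make_vc(0.2, 0.3, 0.5))
        err_share = vc.sigma2_error / vc.total_variance
        assert vc.h_animal + vc.day_share + err_share == pytest.approx(1.0)

    def test_zero_animal_variance_degenerate(self):
        vc = derive_summaries(make_vc(0.0, 0.3, 0.5))
        assert vc.h_animal == 0 and vc.cv == 0 and vc.repeatability == 0

    def test_zero_mean_cv_undefined(self):
        with pytest.raises(ValueError, match="CV undefined"):
            derive_summaries(make_vc(0.1, 0.1, 0.1, mean=0.0))

    def test_denominator_option(self):
        vc = derive_summaries(make_vc(2.0, 1.0, 2.0),
                              repeatability_denominator="total")
        assert vc.repeatability == pytest.approx(0.4)


class TestRepeatabilityWindow:
    def test_full_window_matches_full_fit(self, default_flux):
        spec = ModelSpec("o2")
        full = fit_reml(default_flux, spec).repeatability
        windowed = repeatability_by_window(default_flux, "o2", 17, spec)
        assert windowed == pytest.approx(full)

    def test_two_day_noise_free_window_is_one(self):
        rng = np.random.default_rng(8)
        df = flux_frame(rng, "o2", n_animals=8, n_days=4,
                        params=sim_params("o2", 0.01, 0.002, 0.0))
        assert repeatability_by_window(
            df, "o2", 2, ModelSpec("o2")) == pytest.approx(1.0, abs=1e-4)

    def test_out_of_range_window(self, default_flux):
        with pytest.raises(ValueError):
            repeatability_by_window(default_flux, "o2", 1)
        with pytest.raises(ValueError):
            repeatability_by_window(default_flux, "o2", 18)


class TestLRT:
    def test_identical_specs_stat_zero_p_one(self, default_flux):
        spec = ModelSpec("o2")
        res = lrt_nested(default_flux, spec, spec)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_non_nested_rejected(self, default_flux):
        with pytest.raises(ValueError, match="nested"):
            lrt_nested(default_flux, ModelSpec("o2", random=("animal",)),
                       ModelSpec("o2", random=("day",)))

    def test_type_i_error_near_nominal_under_boundary_mixture(self):
        """Simulating with no day variance, the mixture p-value rejects at
        about the nominal rate."""
        rng = np.random.default_rng(55)
        full = ModelSpec("o2")
        red = ModelSpec("o2", random=("animal",))
        n_rep, alpha = 200, 0.05
        rejections = 0
        params = sim_params("o2", 0.0056, 0.0, 0.0051)
        for _ in range(n_rep):
            df = flux_frame(rng, "o2", n_animals=12, n_days=8, params=params)
            if lrt_nested(df, full, red).pvalue < alpha:
                rejections += 1
        rate = rejections / n_rep
        assert 0.005 <= rate <= 0.12, rate

    def test_power_approaches_one_with_large_day_variance(self):
        rng = np.random.default_rng(56)
        full = ModelSpec("o2")
        red = ModelSpec("o2", random=("animal",))
        params = sim_params("o2", 0.0056, 0.05, 0.0051)
        hits = sum(
            lrt_nested(flux_frame(rng, "o2", n_animals=12, n_days=8,
                                  params=params), full, red).pvalue < 0.05
            for _ in range(30)
        )
        assert hits == 30
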