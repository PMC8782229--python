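"""End-to-end pipeline: simulate (or load) -> flux -> variance components
-> precision -> day consistency -> prediction, with all stage outputs
written as CSV plus a single machine-readable summary."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .day_consistency import day_correlation_matrix, ranking_consistency
from .fluxcalc import flux_table
from .precision import days_for_precision, precision_curve
from .prediction import PredictionSpec, cross_validate
from .synthetic import read_trial, simulate_trial, write_trial
from .validate import validate_input
from .varcomp import (
    ModelSpec,
    fit_reml,
    repeatability_curve,
    varcomp_report,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to ``output_dir``.

    Identical config and seed produce an identical bundle.  A stage
    failure aborts with the stage named; outputs of earlier stages are
    preserved on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"pacflux_version": __version__, "seed": config.seed,
                     "gases": list(config.gases), "stages": {}}

    stage = "simulate"
    try:
        if config.input_trial is not None:
            trial_df = read_trial(config.input_trial)
            logger.info("loaded trial from %s (%d rows)",
                        config.input_trial, len(trial_df))
        else:
            logger.info("simulating trial with seed %d", config.sim_params.seed)
            # drop (rather than abort on) the rare draws whose implied
            # chamber reading is negative; downstream models accept the
            # resulting missing cells
            trial = simulate_trial(config.sim_params, config.design,
                                   on_invalid="drop")
            write_trial(trial, out, include_truth=config.write_truth)
            trial_df = trial.trial
        report = validate_input(trial_df, config.design.chamber_volume_l)
        if not report.ok:
            report.failures.to_csv(out / "validation_failures.csv", index=False)
            raise ValueError(
                f"{report.n_rows - report.n_passed} invalid trial rows "
                f"(see validation_failures.csv)"
            )
        summary["stages"][stage] = {"n_rows": len(trial_df)}

        stage = "flux"
        flux = flux_table(trial_df, gases=config.gases,
                          chamber_volume_l=config.design.chamber_volume_l)
        flux.to_csv(out / "flux.csv", index=False)
        summary["stages"][stage] = {
            gas: {"n": int((flux["gas"] == gas).sum()),
                  "mean_lph": float(flux.loc[flux["gas"] == gas, "flux_lph"].mean()),
                  "mean_gpd": float(flux.loc[flux["gas"] == gas, "flux_gpd"].mean())}
            for gas in config.gases
        }

        stage = "varcomp"
        vcs = [fit_reml(flux, ModelSpec(gas=g, fixed=config.varcomp_fixed))
               for g in config.gases]
        rep_vcs = [fit_reml(flux, ModelSpec(gas=g, fixed=config.repeatability_fixed))
                   for g in config.gases]
        varcomp_report(vcs + rep_vcs).to_csv(out / "varcomp.csv", index=False)
        if config.repeatability_curve:
            pd.concat(
                [repeatability_curve(
                    flux, g, ModelSpec(gas=g, fixed=config.repeatability_fixed))
                 for g in config.gases],
                ignore_index=True,
            ).to_csv(out / "repeatability_curve.csv", index=False)
        summary["stages"][stage] = {
            vc.gas: {"sigma2_animal": vc.sigma2_animal,
                     "sigma2_day": vc.sigma2_day,
                     "sigma2_error": vc.sigma2_error,
                     "h_animal_pct": 100 * vc.h_animal,
                     "cv": vc.cv}
            for vc in vcs
        }
        summary["stages"][stage + "_repeatability"] = {
            vc.gas: vc.repeatability for vc in rep_vcs
        }

        stage = "precision"
        prec_tables = []
        prec_summary = {}
        for vc in vcs:
            curve = precision_curve(vc.sigma2_error, config.precision_n_max, vc.gas)
            prec_tables.append(curve.table)
            entry = {"p_7": float(
                curve.table.loc[curve.table["n"] == 7, "p_n"].iloc[0]
            )} if config.precision_n_max >= 7 else {}
            target = config.precision_targets.get(vc.gas)
            if target is not None:
                entry["days_for_target"] = days_for_precision(
                    vc.sigma2_error, target)
            prec_summary[vc.gas] = entry
        pd.concat(prec_tables, ignore_index=True).to_csv(
            out / "precision.csv", index=False)
        summary["stages"][stage] = prec_summary

        stage = "consistency"
        cons_summary = {}
        for gas in config.gases:
            dm = day_correlation_matrix(flux, gas)
            dm.correlation.to_csv(out / f"day_correlation_{gas}.csv")
            dm.slope.to_csv(out / f"day_slope_{gas}.csv")
            dm.r2.to_csv(out / f"day_r2_{gas}.csv")
            rk = ranking_consistency(flux, gas, config.ranking_k)
            rk.summary.to_csv(out / f"ranking_{gas}.csv", index=False)
            off = dm.correlation.where(
                ~pd.DataFrame(
                    [[i == j for j in range(dm.correlation.shape[1])]
                     for i in range(dm.correlation.shape[0])],
                    index=dm.correlation.index, columns=dm.correlation.columns,
                )
            )
            cons_summary[gas] = {
                "mean_offdiag_corr": float(off.stack().mean()),
                "max_frac_bottom_k": float(rk.summary["frac_bottom_k"].max()),
                "max_frac_top_k": float(rk.summary["frac_top_k"].max()),
            }
        summary["stages"][stage] = cons_summary

        stage = "predict"
        pred_summary = {}
        pred_folds = []
        pred_records = []
        for gas in config.gases:
            res = cross_validate(
                flux, PredictionSpec(gas=gas, n_folds=config.predict_n_folds,
                                     seed=config.seed))
            pf = res.per_fold.copy()
            pf.insert(0, "gas", gas)
            pred_folds.append(pf)
            pr = res.predictions.copy()
            pr.insert(0, "gas", gas)
            pred_records.append(pr)
            pred_summary[gas] = {
                "mean_r2": res.mean_r2, "mean_rmse": res.mean_rmse,
                "pooled_r2": res.pooled_r2, "mean_bias": res.mean_bias,
            }
        pd.concat(pred_folds, ignore_index=True).to_csv(
            out / "prediction_summary.csv", index=False)
        pd.concat(pred_records, ignore_index=True).to_csv(
            out / "predictions.csv", index=False)
        summary["stages"][stage] = pred_summary
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete; bundle written to %s", out)
    return summary
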