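"""Declarative pipeline configuration (YAML) with schema validation.

A config file mirrors the simulation parameters, model specifications and
stage options.  Unknown keys anywhere in the document are rejected before
any computation runs, so typos fail fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .synthetic import DEFAULT_GAS_PARAMS, GasParams, SimParams, TrialDesign


class ConfigError(ValueError):
    pass


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    output_dir: str = "pacflux_out"
    gases: tuple[str, ...] = ("ch4", "o2", "co2")
    input_trial: str | None = None          # path; None -> simulate
    design: TrialDesign = field(default_factory=TrialDesign)
    sim_params: SimParams = field(default_factory=SimParams)
    write_truth: bool = True
    varcomp_fixed: tuple[str, ...] = ()
    repeatability_fixed: tuple[str, ...] = ("liveweight", "humidity")
    repeatability_curve: bool = True
    precision_n_max: int = 17
    precision_targets: dict = field(default_factory=dict)  # gas -> l/h
    ranking_k: int = 10
    predict_n_folds: int = 4
    verbosity: str = "info"


_TOP_KEYS = {
    "seed", "output_dir", "gases", "input_trial", "simulate", "varcomp",
    "repeatability", "precision", "consistency", "predict", "verbosity",
}


def _build_design(d: dict) -> TrialDesign:
    allowed = {f.name for f in fields(TrialDesign)}
    _check_keys(d, allowed, "simulate.design")
    if "reading_times_min" in d:
        d = {**d, "reading_times_min": tuple(d["reading_times_min"])}
    return TrialDesign(**d)


def _build_sim_params(d: dict, seed: int) -> SimParams:
    allowed = {f.name for f in fields(SimParams)}
    _check_keys(d, allowed, "simulate.params")
    d = dict(d)
    if "gases" in d:
        gas_params = dict(DEFAULT_GAS_PARAMS)
        for gas, gd in d["gases"].items():
            _check_keys(gd, {f.name for f in fields(GasParams)},
                        f"simulate.params.gases.{gas}")
            base = gas_params.get(gas.lower())
            gas_params[gas.lower()] = (
                replace(base, **gd) if base is not None else GasParams(**gd)
            )
        d["gases"] = gas_params
    for k in ("breeds", "age_months_range"):
        if k in d:
            d[k] = tuple(d[k])
    d.setdefault("seed", seed)
    return SimParams(**d)


def config_from_dict(doc: dict) -> PipelineConfig:
    """Build and validate a PipelineConfig from a parsed YAML document."""
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    _check_keys(doc, _TOP_KEYS, "top level")
    seed = int(doc.get("seed", 0))
    kwargs: dict = {"seed": seed}
    if "output_dir" in doc:
        kwargs["output_dir"] = str(doc["output_dir"])
    if "gases" in doc:
        kwargs["gases"] = tuple(str(g).lower() for g in doc["gases"])
    if "input_trial" in doc and doc["input_trial"] is not None:
        kwargs["input_trial"] = str(doc["input_trial"])
    if "verbosity" in doc:
        kwargs["verbosity"] = str(doc["verbosity"])

    sim = doc.get("simulate", {}) or {}
    _check_keys(sim, {"design", "params", "write_truth"}, "simulate")
    kwargs["design"] = _build_design(dict(sim.get("design", {}) or {}))
    kwargs["sim_params"] = _build_sim_params(dict(sim.get("params", {}) or {}), seed)
    if "write_truth" in sim:
        kwargs["write_truth"] = bool(sim["write_truth"])

    vc = doc.get("varcomp", {}) or {}
    _check_keys(vc, {"fixed"}, "varcomp")
    if "fixed" in vc:
        kwargs["varcomp_fixed"] = tuple(vc["fixed"])

    rep = doc.get("repeatability", {}) or {}
    _check_keys(rep, {"fixed", "curve"}, "repeatability")
    if "fixed" in rep:
        kwargs["repeatability_fixed"] = tuple(rep["fixed"])
    if "curve" in rep:
        kwargs["repeatability_curve"] = bool(rep["curve"])

    prec = doc.get("precision", {}) or {}
    _check_keys(prec, {"n_max", "targets"}, "precision")
    if "n_max" in prec:
        kwargs["precision_n_max"] = int(prec["n_max"])
    if "targets" in prec:
        kwargs["precision_targets"] = {
            str(g).lower(): float(v) for g, v in prec["targets"].items()
        }

    cons = doc.get("consistency", {}) or {}
    _check_keys(cons, {"k"}, "consistency")
    if "k" in cons:
        kwargs["ranking_k"] = int(cons["k"])

    pred = doc.get("predict", {}) or {}
    _check_keys(pred, {"n_folds"}, "predict")
    if "n_folds" in pred:
        kwargs["predict_n_folds"] = int(pred["n_folds"])

    return PipelineConfig(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
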