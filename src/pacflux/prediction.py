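"""Mixed-model prediction of gaseous output, evaluated by stratified
k-fold cross-validation.

The prediction equation regresses per-record flux (l/h) on measurement
day, run group and breed (class effects) plus age, liveweight, humidity,
temperature and pressure (covariates), with a random animal effect.  For
each fold, variance components are re-estimated on the training records
by REML, fixed effects and animal BLUPs come from the mixed-model
equations, and held-out records are predicted as fixed part + animal BLUP
(fixed part only for animals absent from training).  Fit quality is the
squared Pearson correlation between held-out predictions and actuals
(r^2) and the RMSE, per fold and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from ._reml import RandomFactor, reml_fit
from .constants import check_gas

DEFAULT_CLASS_EFFECTS = ("day_index", "run_index", "breed")
DEFAULT_COVARIATES = (
    "age_months", "liveweight_kg", "humidity_pct", "temp_c", "pressure_hpa"
)


@dataclass(frozen=True)
class PredictionSpec:
    gas: str
    class_effects: tuple[str, ...] = DEFAULT_CLASS_EFFECTS
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    n_folds: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "gas", check_gas(self.gas))
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class PredictionResult:
    """Cross-validation outcome for one gas."""

    gas: str
    per_fold: pd.DataFrame        # fold, n, r2, rmse, pred_mean, actual_mean, bias
    mean_r2: float
    mean_rmse: float
    mean_pred: float
    mean_bias: float              # mean(predicted) - mean(actual), pooled
    pooled_r2: float
    pooled_rmse: float
    predictions: pd.DataFrame     # record-level: fold, actual, predicted, flags
    variance_components: list = field(default_factory=list)


def make_folds(data: pd.DataFrame, spec: PredictionSpec) -> np.ndarray:
    """Fold assignment stratified by animal and measurement date.

    Records are grouped by animal and dealt round-robin into folds from a
    per-animal starting fold; animal order and within-animal record order
    are seeded permutations and starting folds rotate across animals, so
    the split is deterministic given the seed, fold sizes differ by at
    most one, and each animal's records are spread across folds.
    """
    n = len(data)
    if n < spec.n_folds:
        raise ValueError(f"{n} records cannot fill {spec.n_folds} folds")
    rng = np.random.default_rng(spec.seed)
    folds = np.empty(n, dtype=int)
    groups = list(data.groupby("animal_id", sort=True).indices.items())
    order = rng.permutation(len(groups))
    # balanced starting offsets: each fold receives the same number of
    # animals' "extra" records (up to remainder)
    offsets = np.tile(np.arange(spec.n_folds), len(groups) // spec.n_folds + 1)
    for pos, gi in enumerate(order):
        _, idx = groups[gi]
        idx = np.asarray(idx)
        idx = idx[rng.permutation(len(idx))]
        start = offsets[pos]
        folds[idx] = (start + np.arange(len(idx))) % spec.n_folds
    # rebalance if animal sizes left folds uneven by more than one
    counts = np.bincount(folds, minlength=spec.n_folds)
    while counts.max() - counts.min() > 1:
        big, small = int(counts.argmax()), int(counts.argmin())
        movable = np.where(folds == big)[0]
        folds[rng.choice(movable)] = small
        counts = np.bincount(folds, minlength=spec.n_folds)
    return folds


def _full_rank_columns(X: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent column subset."""
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return np.sort(piv[:rank])


def _design_frames(
    train: pd.DataFrame, test: pd.DataFrame, spec: PredictionSpec
):
    """Consistent fixed-effect design for train and test.

    Class effects are dummy-coded against the first level seen in the
    combined data; columns collinear on the training rows (including
    levels absent from training) are dropped, which predicts such levels
    at the reference level.  Test records carrying a class level unseen in
    training are flagged.
    """
    need = list(spec.class_effects) + list(spec.covariates)
    missing = [c for c in need if c not in train.columns]
    if missing:
        raise ValueError(f"prediction covariates missing from data: {missing}")
    combined = pd.concat([train[need], test[need]], keys=["train", "test"])
    parts = [pd.Series(1.0, index=combined.index, name="intercept")]
    for c in spec.class_effects:
        dummies = pd.get_dummies(
            combined[c].astype("category"), prefix=c, drop_first=True, dtype=float
        )
        parts.append(dummies)
    for c in spec.covariates:
        parts.append(combined[c].astype(float))
    M = pd.concat(parts, axis=1)
    Xtr = M.loc["train"].to_numpy(float)
    Xte = M.loc["test"].to_numpy(float)
    keep = _full_rank_columns(Xtr)
    names = [M.columns[i] for i in keep]

    flags = np.full(len(test), "", dtype=object)
    for c in spec.class_effects:
        seen = set(train[c].unique())
        unseen = ~test[c].isin(seen).to_numpy()
        if unseen.any():
            flags[unseen] = np.where(
                flags[unseen] == "", f"unseen_{c}",
                flags[unseen] + f";unseen_{c}",
            )
    return Xtr[:, keep], Xte[:, keep], names, flags


def fit_and_predict(
    train: pd.DataFrame, test: pd.DataFrame, spec: PredictionSpec
) -> pd.DataFrame:
    """Fit on ``train`` and predict ``test`` fluxes.

    Returns the test frame's keys with columns ``actual``, ``predicted``
    and ``flags`` (record-level notes: unseen class levels, unseen animal).
    """
    train = _gas_rows(train, spec.gas)
    test = _gas_rows(test, spec.gas)
    Xtr, Xte, names, flags = _design_frames(train, test, spec)
    y = train["flux_lph"].to_numpy(float)
    animal = RandomFactor.from_labels("animal", train["animal_id"].to_numpy())
    res = reml_fit(y, Xtr, [animal], beta_names=names, compute_se=False)

    pred = Xte @ res.beta
    blup = res.blups["animal"]
    test_animals = test["animal_id"].to_numpy()
    u = np.array([blup.get(a, 0.0) for a in test_animals])
    unseen_animal = ~np.isin(test_animals, animal.levels)
    if unseen_animal.any():
        flags[unseen_animal] = np.where(
            flags[unseen_animal] == "", "unseen_animal",
            flags[unseen_animal] + ";unseen_animal",
        )
    out = test[["animal_id", "day_index"]].copy()
    out["actual"] = test["flux_lph"].to_numpy(float)
    out["predicted"] = pred + u
    out["flags"] = flags
    out.attrs["variances"] = res.all_variances
    return out


def _gas_rows(df: pd.DataFrame, gas: str) -> pd.DataFrame:
    sub = df[df["gas"] == gas] if "gas" in df.columns else df
    if sub.empty:
        raise ValueError(f"no records for gas {gas!r}")
    return sub.reset_index(drop=True)


def _r2(actual: np.ndarray, predicted: np.ndarray) -> float:
    if np.std(actual) == 0 or np.std(predicted) == 0:
        return 0.0
    return float(np.corrcoef(actual, predicted)[0, 1] ** 2)


def cross_validate(data: pd.DataFrame, spec: PredictionSpec) -> PredictionResult:
    """Stratified k-fold cross-validation of the prediction equation."""
    df = _gas_rows(data, spec.gas)
    folds = make_folds(df, spec)
    fold_rows = []
    pred_frames = []
    variances = []
    for f in range(spec.n_folds):
        test_mask = folds == f
        preds = fit_and_predict(df[~test_mask], df[test_mask], spec)
        preds.insert(0, "fold", f)
        pred_frames.append(preds)
        variances.append(preds.attrs.get("variances", {}))
        a, p = preds["actual"].to_numpy(), preds["predicted"].to_numpy()
        fold_rows.append({
            "fold": f,
            "n": int(test_mask.sum()),
            "r2": _r2(a, p),
            "rmse": float(np.sqrt(np.mean((a - p) ** 2))),
            "pred_mean": float(p.mean()),
            "actual_mean": float(a.mean()),
            "bias": float(p.mean() - a.mean()),
        })
    per_fold = pd.DataFrame(fold_rows)
    predictions = pd.concat(pred_frames, ignore_index=True)
    a = predictions["actual"].to_numpy()
    p = predictions["predicted"].to_numpy()
    return PredictionResult(
        gas=spec.gas,
        per_fold=per_fold,
        mean_r2=float(per_fold["r2"].mean()),
        mean_rmse=float(per_fold["rmse"].mean()),
        mean_pred=float(per_fold["pred_mean"].mean()),
        mean_bias=float(p.mean() - a.mean()),
        pooled_r2=_r2(a, p),
        pooled_rmse=float(np.sqrt(np.mean((a - p) ** 2))),
        predictions=predictions,
        variance_components=variances,
    )
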