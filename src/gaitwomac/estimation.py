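"""WOMAC estimation from key features: balancing, hold-out, linear and
random-forest regression.

The protocol: random under-sampling removes subjects only from the largest
severity classes until the cohort reaches the balance target (231 by
default — (140, 182, 53) becomes (89, 89, 53)); a stratified 70/30 hold-out
split follows; models are ordinary least squares (with intercept) and a
bagged random forest (500 trees, one-third of the features per split,
minimum leaf 5).  Reported metrics are RMSE in WOMAC points and the Pearson
correlation between actual and estimated scores.  The random forest is
validated on the hold-out set; for the linear model both in-sample and
hold-out metrics are reported, clearly labelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg as sp_linalg
from sklearn.ensemble import RandomForestRegressor

from .errors import UndefinedStatisticError, ValidationError

DEFAULT_BALANCE_TARGET = 231
DEFAULT_TRAIN_FRACTION = 0.70

DEFAULT_RF_PARAMS = {
    "n_estimators": 500,
    "max_features": 1 / 3,
    "max_depth": None,
    "min_samples_leaf": 5,
}


@dataclass
class ModelReport:
    """Fitted-model metadata plus evaluation metrics."""

    model_kind: str
    n_train: int
    n_test: int
    rmse: float
    pearson_r: float
    seed: Optional[int] = None
    hyperparameters: Dict = field(default_factory=dict)
    coefficients: Optional[pd.Series] = None
    predictions: Optional[pd.DataFrame] = None  # subject_id, actual, predicted, split
    in_sample_rmse: Optional[float] = None
    in_sample_pearson_r: Optional[float] = None

    def __post_init__(self):
        if self.rmse < 0 or (np.isfinite(self.pearson_r) and abs(self.pearson_r) > 1 + 1e-12):
            raise ValidationError("invalid metrics: rmse >= 0 and |r| <= 1 required")


def greedy_balanced_sizes(class_sizes: Dict[str, int], target_total: int) -> Dict[str, int]:
    """Class sizes after trimming the current largest class one subject at a
    time until the total reaches ``target_total`` (minority classes stay
    intact): (140, 182, 53) -> (89, 89, 53) at target 231."""
    if target_total < len(class_sizes):
        raise ValidationError("target must keep at least one subject per class")
    total = sum(class_sizes.values())
    if target_total > total:
        raise ValidationError(f"target {target_total} exceeds cohort size {total}")
    sizes = dict(class_sizes)
    names = sorted(sizes)  # deterministic tie-break
    while sum(sizes.values()) > target_total:
        largest = max(names, key=lambda g: sizes[g])
        sizes[largest] -= 1
    return sizes


def balance_downsample(
    subject_ids: Sequence[str],
    classes: Sequence[str],
    target_total: int = DEFAULT_BALANCE_TARGET,
    seed: int = 0,
) -> List[str]:
    """Random under-sampling without replacement, removing subjects only
    from the largest classes (greedy trimming); deterministic per seed."""
    ids = np.asarray(subject_ids)
    labels = np.asarray(classes)
    if ids.shape != labels.shape:
        raise ValidationError("subject_ids and classes must align")
    counts = {g: int((labels == g).sum()) for g in np.unique(labels)}
    targets = greedy_balanced_sizes(counts, target_total)
    rng = np.random.default_rng(seed)
    kept: List[str] = []
    for g in sorted(targets):
        members = ids[labels == g]
        chosen = rng.choice(members, size=targets[g], replace=False)
        kept.extend(chosen.tolist())
    order = {sid: i for i, sid in enumerate(subject_ids)}
    return sorted(kept, key=order.get)


def holdout_split(
    subject_ids: Sequence[str],
    classes: Optional[Sequence[str]] = None,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
    stratify: bool = True,
) -> Tuple[List[str], List[str]]:
    """Random train/test partition with train size round(fraction * n),
    stratified by severity class by default so every class appears on both
    sides."""
    ids = list(subject_ids)
    n = len(ids)
    if not (0.0 < train_fraction < 1.0):
        raise ValidationError("train_fraction must lie strictly between 0 and 1")
    if n < 10:
        raise ValidationError("hold-out requires at least 10 subjects")
    n_train = int(round(train_fraction * n))
    rng = np.random.default_rng(seed)
    if not stratify or classes is None:
        perm = rng.permutation(n)
        train_idx = set(perm[:n_train].tolist())
    else:
        labels = np.asarray(classes)
        raw = {}
        for g in sorted(np.unique(labels)):
            idx = np.flatnonzero(labels == g)
            raw[g] = (idx, train_fraction * idx.size)
        base = {g: int(np.floor(v)) for g, (idx, v) in raw.items()}
        short = n_train - sum(base.values())
        by_frac = sorted(raw, key=lambda g: (-(raw[g][1] - base[g]), g))
        for g in by_frac[:short]:
            base[g] += 1
        train_idx = set()
        for g, (idx, _) in raw.items():
            chosen = rng.choice(idx, size=base[g], replace=False)
            train_idx.update(chosen.tolist())
    train = [sid for i, sid in enumerate(ids) if i in train_idx]
    test = [sid for i, sid in enumerate(ids) if i not in train_idx]
    return train, test


def evaluate(predictions: Sequence[float], actual: Sequence[float]) -> Tuple[float, float]:
    """(RMSE, Pearson r) between predicted and actual scores.

    Constant actuals make the correlation undefined; the RMSE is still
    meaningful, so the caller may catch :class:`UndefinedStatisticError`
    and keep it.
    """
    pred = np.asarray(predictions, dtype=float)
    act = np.asarray(actual, dtype=float)
    if pred.shape != act.shape or pred.ndim != 1 or pred.size < 3:
        raise ValidationError("predictions and actuals must be equal-length 1-D, length >= 3")
    rmse = float(np.sqrt(np.mean((pred - act) ** 2)))
    if np.std(act) == 0:
        raise UndefinedStatisticError(f"pearson r undefined for constant actuals (rmse={rmse})")
    if np.std(pred) == 0:
        return rmse, 0.0
    r = float(np.corrcoef(pred, act)[0, 1])
    return rmse, r


def _check_design(X: pd.DataFrame, y: np.ndarray) -> None:
    if X.isna().any().any():
        raise ValidationError("design matrix contains missing values")
    if X.shape[0] != y.shape[0]:
        raise ValidationError("X and y must have the same number of rows")


def fit_linear(
    X_train: pd.DataFrame,
    y_train: Sequence[float],
    on_collinear: str = "error",
) -> Tuple[pd.Series, float]:
    """Ordinary least squares with intercept.

    Returns (coefficients indexed by feature id, intercept).  A numerically
    rank-deficient design raises an error naming the collinear columns;
    ``on_collinear='pinv'`` falls back to the minimum-norm pseudo-inverse
    solution instead.
    """
    y = np.asarray(y_train, dtype=float)
    _check_design(X_train, y)
    if X_train.shape[0] <= X_train.shape[1] and on_collinear == "error":
        raise ValidationError(
            f"need more training subjects ({X_train.shape[0]}) than features "
            f"({X_train.shape[1]}); reduce the feature set first"
        )
    A = np.column_stack([np.ones(X_train.shape[0]), X_train.values])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        if on_collinear == "error":
            # name suspects via pivoted QR: columns beyond the numerical rank
            _, _, piv = sp_linalg.qr(A, pivoting=True)
            suspects = [
                X_train.columns[j - 1] for j in piv[rank:] if j > 0
            ]
            raise ValidationError(f"rank-deficient design; collinear columns: {suspects}")
        if on_collinear != "pinv":
            raise ValidationError(f"unknown on_collinear mode {on_collinear!r}")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    coefs = pd.Series(beta[1:], index=X_train.columns, name="coefficient")
    return coefs, float(beta[0])


def predict_linear(X: pd.DataFrame, coefs: pd.Series, intercept: float) -> np.ndarray:
    return X[coefs.index].values @ coefs.values + intercept


def fit_random_forest(
    X_train: pd.DataFrame,
    y_train: Sequence[float],
    hyperparameters: Optional[Dict] = None,
    seed: int = 0,
) -> RandomForestRegressor:
    """Bagged regression trees with feature subsampling; seeded and
    reproducible."""
    y = np.asarray(y_train, dtype=float)
    _check_design(X_train, y)
    params = dict(DEFAULT_RF_PARAMS)
    if hyperparameters:
        params.update(hyperparameters)
    model = RandomForestRegressor(random_state=seed, **params)
    model.fit(X_train.values, y)
    return model


def run_estimation(
    X: pd.DataFrame,
    womac_totals: pd.Series,
    classes: pd.Series,
    balance_target: int = DEFAULT_BALANCE_TARGET,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    balance_seed: int = 0,
    split_seed: int = 1,
    forest_seed: int = 2,
    linear_max_features: Optional[int] = 20,
    feature_order: Optional[Sequence[str]] = None,
    rf_params: Optional[Dict] = None,
    on_collinear: str = "pinv",
) -> Dict[str, ModelReport]:
    """Balanced hold-out estimation with both model families.

    ``feature_order`` (e.g. key features by ascending ANOVA p) controls
    which columns the linear model keeps when ``linear_max_features`` caps
    the design; the forest always uses all columns.
    """
    ids = list(X.index)
    balanced = balance_downsample(ids, classes.loc[ids], balance_target, seed=balance_seed)
    Xb = X.loc[balanced]
    yb = womac_totals.loc[balanced]
    cb = classes.loc[balanced]
    train, test = holdout_split(balanced, cb, train_fraction, seed=split_seed)

    cols = list(X.columns if feature_order is None else feature_order)
    lin_cols = cols if linear_max_features is None else cols[:linear_max_features]

    reports: Dict[str, ModelReport] = {}

    coefs, intercept = fit_linear(Xb.loc[train, lin_cols], yb.loc[train], on_collinear)
    pred_test = predict_linear(Xb.loc[test, lin_cols], coefs, intercept)
    pred_train = predict_linear(Xb.loc[train, lin_cols], coefs, intercept)
    rmse, r = evaluate(pred_test, yb.loc[test])
    rmse_in, r_in = evaluate(pred_train, yb.loc[train])
    reports["linear"] = ModelReport(
        model_kind="linear",
        n_train=len(train),
        n_test=len(test),
        rmse=rmse,
        pearson_r=r,
        hyperparameters={"max_features": linear_max_features, "on_collinear": on_collinear},
        coefficients=coefs,
        predictions=_prediction_frame(train, test, yb, pred_train, pred_test),
        in_sample_rmse=rmse_in,
        in_sample_pearson_r=r_in,
    )

    forest = fit_random_forest(Xb.loc[train, cols], yb.loc[train], rf_params, seed=forest_seed)
    rf_test = forest.predict(Xb.loc[test, cols].values)
    rf_train = forest.predict(Xb.loc[train, cols].values)
    rmse, r = evaluate(rf_test, yb.loc[test])
    reports["random_forest"] = ModelReport(
        model_kind="random_forest",
        n_train=len(train),
        n_test=len(test),
        rmse=rmse,
        pearson_r=r,
        seed=forest_seed,
        hyperparameters={**DEFAULT_RF_PARAMS, **(rf_params or {})},
        predictions=_prediction_frame(train, test, yb, rf_train, rf_test),
    )
    return reports


def _prediction_frame(train, test, y, pred_train, pred_test) -> pd.DataFrame:
    rows = [
        pd.DataFrame(
            {"subject_id": train, "actual": y.loc[train].values, "predicted": pred_train,
             "split": "train"}
        ),
        pd.DataFrame(
            {"subject_id": test, "actual": y.loc[test].values, "predicted": pred_test,
             "split": "test"}
        ),
    ]
    return pd.concat(rows, ignore_index=True)
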