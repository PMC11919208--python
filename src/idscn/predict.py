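"""Symptom-severity prediction from edge Z features.

A random-forest regressor is evaluated under repeated nested
cross-validation: the outer folds provide held-out predictions, the inner
folds select forest hyperparameters by grid search, and the whole procedure
is repeated with reshuffled folds. Per-patient predictions come only from
folds where the patient was held out; the headline correlation is computed
on predictions averaged over repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold


@dataclass
class PredictionReport:
    observed: np.ndarray
    predicted: np.ndarray          # averaged over repeats
    per_repeat_mae: np.ndarray
    per_repeat_mse: np.ndarray
    per_repeat_r: np.ndarray
    mae: float                     # pooled over repeats
    mse: float
    r: float                       # nan when undefined (constant inputs)
    r_p: float

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "mse": self.mse,
            "r": None if np.isnan(self.r) else self.r,
            "r_p": None if np.isnan(self.r_p) else self.r_p,
            "per_repeat_mae": self.per_repeat_mae.tolist(),
            "per_repeat_mse": self.per_repeat_mse.tolist(),
        }


def _default_grid(n_features: int) -> dict:
    mf = sorted({max(1, int(np.ceil(n_features / 3))),
                 max(1, int(np.ceil(np.sqrt(n_features)))),
                 n_features})
    return {"max_features": mf, "min_samples_leaf": [1, 5]}


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def nested_cv_predict(
    features: np.ndarray,
    targets: np.ndarray,
    outer_folds: int = 10,
    inner_folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    n_estimators: int = 500,
    mean_feature_mode: bool = False,
) -> PredictionReport:
    """Repeated nested-CV random-forest prediction of symptom scores.

    Each repeat reshuffles the outer/inner fold assignment from the seeded
    RNG. Within every outer training set, an inner grid search (features per
    split, minimum leaf size) selects the forest by CV mean-squared error;
    held-out outer predictions are collected per repeat. ``mean_feature_mode``
    collapses the feature matrix to a single per-patient mean across edges.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be patients x edges matching targets")
    if not np.all(np.isfinite(y)):
        raise ValueError("targets must be finite")
    n = X.shape[0]
    if n < outer_folds:
        raise ValueError(f"need at least {outer_folds} patients for the outer split")
    if mean_feature_mode:
        X = X.mean(axis=1, keepdims=True)
    grid = _default_grid(X.shape[1])

    ss = np.random.SeedSequence(seed)
    repeat_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(repeats)]

    all_preds = np.empty((repeats, n))
    mae = np.empty(repeats)
    mse = np.empty(repeats)
    r_rep = np.empty(repeats)
    for rep in range(repeats):
        rs = repeat_seeds[rep]
        outer = KFold(n_splits=outer_folds, shuffle=True, random_state=rs)
        preds = np.empty(n)
        for fold, (train, test) in enumerate(outer.split(X)):
            inner = KFold(n_splits=inner_folds, shuffle=True,
                          random_state=rs + fold + 1)
            search = GridSearchCV(
                RandomForestRegressor(n_estimators=n_estimators, random_state=rs),
                grid, cv=inner, scoring="neg_mean_squared_error", n_jobs=None,
            )
            search.fit(X[train], y[train])
            preds[test] = search.best_estimator_.predict(X[test])
        all_preds[rep] = preds
        err = preds - y
        mae[rep] = np.mean(np.abs(err))
        mse[rep] = np.mean(err ** 2)
        r_rep[rep] = _safe_pearson(preds, y)[0]

    mean_pred = all_preds.mean(axis=0)
    r, r_p = _safe_pearson(mean_pred, y)
    pooled_err = all_preds - y[None, :]
    return PredictionReport(
        observed=y,
        predicted=mean_pred,
        per_repeat_mae=mae,
        per_repeat_mse=mse,
        per_repeat_r=r_rep,
        mae=float(np.mean(np.abs(pooled_err))),
        mse=float(np.mean(pooled_err ** 2)),
        r=r,
        r_p=r_p,
    )
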