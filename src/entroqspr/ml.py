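"""Cross-validated machine-learning regression on entropy-descriptor tables.

Random Forest, support-vector and gradient-boosting regressors over the
descriptor matrix, with standardization, feature selection (recursive
elimination or PCA projection) and seeded k-fold evaluation.  With only
a dozen real compounds these models are exploratory — the module exists
to make the ML stage of the pipeline reproducible and property-testable
on synthetic data, where ground truth is known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.feature_selection import RFE
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.svm import SVR

__all__ = ["MLEvaluation", "MODEL_KINDS", "preprocess", "select_features", "cv_evaluate"]

MODEL_KINDS = ("rf", "svm", "gbm")


@dataclass(frozen=True)
class MLEvaluation:
    """Per-fold and aggregate metrics of one cross-validated model."""

    model_kind: str
    folds: int
    seed: int
    fold_mse: tuple[float, ...]
    fold_rmse: tuple[float, ...]
    fold_r2: tuple[float, ...]
    features: tuple[str, ...]

    @property
    def mse(self) -> float:
        return float(np.mean(self.fold_mse))

    @property
    def rmse(self) -> float:
        return float(np.mean(self.fold_rmse))

    @property
    def r2(self) -> float:
        return float(np.mean(self.fold_r2))

    def to_dict(self) -> dict:
        return {
            "model": self.model_kind,
            "folds": self.folds,
            "seed": self.seed,
            "mse": self.mse,
            "rmse": self.rmse,
            "r2": self.r2,
            "fold_mse": list(self.fold_mse),
            "fold_rmse": list(self.fold_rmse),
            "fold_r2": list(self.fold_r2),
            "features": list(self.features),
        }


def preprocess(table: pd.DataFrame) -> pd.DataFrame:
    """Center and scale every column to mean 0, sd 1 (ddof=0).

    Zero-variance columns carry no information and are dropped with a
    warning; a table with no informative column is rejected.
    """
    if table.empty:
        raise ValueError("empty table")
    sd = table.std(ddof=0)
    dead = list(sd.index[sd == 0.0])
    if dead:
        warnings.warn(f"dropping zero-variance column(s): {dead}", stacklevel=2)
    kept = table.drop(columns=dead)
    if kept.shape[1] == 0:
        raise ValueError("all columns have zero variance")
    return (kept - kept.mean()) / kept.std(ddof=0)


def _estimator(kind: str, seed: int):
    if kind == "rf":
        return RandomForestRegressor(n_estimators=200, random_state=seed)
    if kind == "svm":
        return SVR(kernel="rbf", C=10.0)
    if kind == "gbm":
        return GradientBoostingRegressor(random_state=seed)
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


def select_features(
    table: pd.DataFrame,
    target: Sequence[float],
    method: str = "rfe",
    k: int = 3,
    seed: int = 0,
):
    """Rank or project features before model fitting.

    ``rfe`` recursively eliminates features under a linear model and
    returns the selected column names in ranking order; ``pca`` returns
    (projected table, explained variance ratios) for the first k
    principal components.  Deterministic given the seed.
    """
    if not (1 <= k <= table.shape[1]):
        raise ValueError(f"k must be in [1, {table.shape[1]}], got {k}")
    y = np.asarray(target, dtype=float)
    if method == "rfe":
        rfe = RFE(LinearRegression(), n_features_to_select=k)
        rfe.fit(table.to_numpy(), y)
        order = np.argsort(rfe.ranking_, kind="stable")
        ranked = [table.columns[i] for i in order]
        return ranked[:k]
    if method == "pca":
        pca = PCA(n_components=k, random_state=seed)
        proj = pca.fit_transform(table.to_numpy())
        cols = [f"PC{i + 1}" for i in range(k)]
        return (
            pd.DataFrame(proj, index=table.index, columns=cols),
            pca.explained_variance_ratio_,
        )
    raise ValueError(f"unknown method {method!r}; expected 'rfe' or 'pca'")


def cv_evaluate(
    model_kind: str,
    features: pd.DataFrame,
    target: Sequence[float],
    folds: int = 5,
    seed: int = 0,
) -> MLEvaluation:
    """Seeded k-fold fit/predict with MSE, RMSE and R^2 per fold."""
    y = np.asarray(target, dtype=float)
    n = len(y)
    if features.shape[0] != n:
        raise ValueError("features/target length mismatch")
    if not (2 <= folds <= n):
        raise ValueError(f"folds must satisfy 2 <= folds <= n={n}, got {folds}")
    X = features.to_numpy(dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    mses, rmses, r2s = [], [], []
    for train, test in kf.split(X):
        est = _estimator(model_kind, seed)
        est.fit(X[train], y[train])
        pred = est.predict(X[test])
        err = y[test] - pred
        mse = float(np.mean(err ** 2))
        sst = float(((y[test] - y[test].mean()) ** 2).sum())
        r2 = 1.0 - float((err ** 2).sum()) / sst if sst > 0 else 0.0
        mses.append(mse)
        rmses.append(float(np.sqrt(mse)))
        r2s.append(r2)
    return MLEvaluation(
        model_kind=model_kind,
        folds=folds,
        seed=seed,
        fold_mse=tuple(mses),
        fold_rmse=tuple(rmses),
        fold_r2=tuple(r2s),
        features=tuple(features.columns),
    )
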