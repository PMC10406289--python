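"""Per-metric regression surrogates of the simulation, plus PCA diagnostics.

For each of the 12 acquisition metrics, three model types — support vector
regression, k-nearest-neighbor regression and a random forest — are tuned by
random search (default budget 200 draws per type) scored with 10-fold
cross-validated RMSE on the training partition.  The tuned candidates are
compared on the test partition; the winner alone is evaluated on the
validation partition (three-way holdout: validation rows never influence
tuning or selection).  Hyperparameter ranges: kNN Minkowski distance
exponent in [0.1, 20] and neighbor-weighting kernel; SVR stopping tolerance
in [0.001, 0.9], epsilon in [0.1, 0.9] and kernel; random forest max depth
in {0..20} (0 = unlimited) and 1-20 trees.  Inputs are the 10 numeric
sequence parameters, z-scored inside the SVR/kNN pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .dataset import METRIC_COLUMNS, NUMERIC_COLUMNS
from .metrics import METRIC_FIELDS, AcquisitionMetrics

__all__ = [
    "HyperparameterSpace",
    "SurrogateModel",
    "PCAResult",
    "error_metrics",
    "tune",
    "fit_model",
    "select_and_validate",
    "predict",
    "pca",
    "MODEL_TYPES",
]

MODEL_TYPES = ("svr", "knn", "rf")


@dataclass(frozen=True)
class HyperparameterSpace:
    knn_p: Tuple[float, float] = (0.1, 20.0)
    knn_kernels: Tuple[str, ...] = ("rectangular", "triangular", "gaussian")
    svr_tol: Tuple[float, float] = (0.001, 0.9)
    svr_epsilon: Tuple[float, float] = (0.1, 0.9)
    svr_kernels: Tuple[str, ...] = ("rbf", "linear", "poly")
    rf_max_depth: Tuple[int, int] = (0, 20)
    rf_n_trees: Tuple[int, int] = (1, 20)
    budget: int = 200  # random-search evaluations per model type


@dataclass
class SurrogateModel:
    metric: str
    model_type: str
    params: dict
    estimator: object
    test_errors: Dict[str, float]
    validation_errors: Dict[str, float] = field(default_factory=dict)
    cv_rmse: float = np.nan
    seed: Optional[int] = None


@dataclass
class PCAResult:
    std_deviation: np.ndarray
    proportion: np.ndarray
    cumulative: np.ndarray
    columns: List[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        comps = [f"PC{i + 1}" for i in range(len(self.std_deviation))]
        return pd.DataFrame(
            [self.std_deviation, self.proportion, self.cumulative],
            index=["Std. deviation", "Proportion", "Cum. prop."],
            columns=comps,
        )


# --------------------------------------------------------------------------
# error metrics
# --------------------------------------------------------------------------


def error_metrics(y, yhat) -> Tuple[float, float, float]:
    """(rmse, rrse, rmsle).

    rmse = sqrt(mean((yhat - y)^2));
    rrse = sqrt(sum((yhat - y)^2) / sum((y - mean(y))^2)), i.e. error relative
    to the constant-mean predictor (exactly 1 for that predictor);
    rmsle = sqrt(mean((log1p(yhat) - log1p(y))^2)), NaN if any value <= -1.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    err = yhat - y
    rmse = float(np.sqrt(np.mean(err**2)))
    denom = np.sum((y - y.mean()) ** 2)
    if denom == 0:
        raise ValueError("rrse undefined for a constant target")
    rrse = float(np.sqrt(np.sum(err**2) / denom))
    if np.any(y <= -1) or np.any(yhat <= -1):
        rmsle = float("nan")
    else:
        rmsle = float(np.sqrt(np.mean((np.log1p(yhat) - np.log1p(y)) ** 2)))
    return rmse, rrse, rmsle


# --------------------------------------------------------------------------
# models
# --------------------------------------------------------------------------


def _weights_rectangular(dist: np.ndarray) -> np.ndarray:
    return np.ones_like(dist)


def _weights_triangular(dist: np.ndarray) -> np.ndarray:
    dmax = dist.max(axis=1, keepdims=True) + 1e-12
    return np.clip(1.0 - dist / dmax, 1e-9, None)


def _weights_gaussian(dist: np.ndarray) -> np.ndarray:
    dmax = dist.max(axis=1, keepdims=True) + 1e-12
    return np.exp(-0.5 * (2.0 * dist / dmax) ** 2) + 1e-12


_KNN_KERNELS = {
    "rectangular": "uniform",  # sklearn fast path
    "triangular": _weights_triangular,
    "gaussian": _weights_gaussian,
}


def sample_params(model_type: str, space: HyperparameterSpace, rng: np.random.Generator) -> dict:
    if model_type == "knn":
        return {
            "p": float(rng.uniform(*space.knn_p)),
            "kernel": str(rng.choice(space.knn_kernels)),
        }
    if model_type == "svr":
        return {
            "tol": float(rng.uniform(*space.svr_tol)),
            "epsilon": float(rng.uniform(*space.svr_epsilon)),
            "kernel": str(rng.choice(space.svr_kernels)),
        }
    if model_type == "rf":
        return {
            "max_depth": int(rng.integers(space.rf_max_depth[0], space.rf_max_depth[1] + 1)),
            "n_trees": int(rng.integers(space.rf_n_trees[0], space.rf_n_trees[1] + 1)),
        }
    raise ValueError(f"unknown model type {model_type!r}")


def make_estimator(model_type: str, params: dict, n_train: int, seed: int = 0):
    """Build an (unfitted) sklearn estimator for one hyperparameter draw."""
    if model_type == "knn":
        model = KNeighborsRegressor(
            n_neighbors=params.get("n_neighbors", min(7, max(1, n_train - 1))),
            p=params["p"],
            weights=_KNN_KERNELS[params["kernel"]],
            algorithm="brute",  # required for Minkowski exponents below 1
        )
        return Pipeline([("scale", StandardScaler()), ("model", model)])
    if model_type == "svr":
        model = SVR(kernel=params["kernel"], tol=params["tol"], epsilon=params["epsilon"])
        return Pipeline([("scale", StandardScaler()), ("model", model)])
    if model_type == "rf":
        depth = params["max_depth"] or None  # 0 means unlimited
        return RandomForestRegressor(
            n_estimators=params["n_trees"], max_depth=depth, random_state=seed
        )
    raise ValueError(f"unknown model type {model_type!r}")


def _cv_rmse(model_type, params, X, y, n_folds, seed) -> float:
    folds = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errors = []
    for train_idx, test_idx in folds.split(X):
        est = make_estimator(model_type, params, len(train_idx), seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X[train_idx], y[train_idx])
            pred = est.predict(X[test_idx])
        errors.append(np.mean((pred - y[test_idx]) ** 2))
    return float(np.sqrt(np.mean(errors)))


def tune(
    model_type: str,
    X: np.ndarray,
    y: np.ndarray,
    space: HyperparameterSpace,
    seed: int = 0,
    n_folds: int = 10,
) -> Tuple[dict, float]:
    """Random hyperparameter search scored by k-fold CV mean RMSE.

    Returns (best params, best CV RMSE); deterministic under ``seed``.
    """
    if space.budget < 1:
        raise ValueError("search budget must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n_folds = min(n_folds, len(y))
    rng = np.random.default_rng(seed)
    best_params, best_score = None, np.inf
    for _ in range(space.budget):
        params = sample_params(model_type, space, rng)
        score = _cv_rmse(model_type, params, X, y, n_folds, seed)
        if score < best_score:
            best_params, best_score = params, score
    return best_params, best_score


def fit_model(model_type: str, params: dict, X, y, seed: int = 0):
    est = make_estimator(model_type, params, len(y), seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
    return est


# --------------------------------------------------------------------------
# selection with three-way holdout
# --------------------------------------------------------------------------


def _partition(table: pd.DataFrame, label: str):
    part = table[table["split"] == label]
    return part[NUMERIC_COLUMNS].to_numpy(float), part


def select_and_validate(
    table: pd.DataFrame,
    space: Optional[HyperparameterSpace] = None,
    seed: int = 0,
    metric_columns: Optional[List[str]] = None,
) -> Dict[str, SurrogateModel]:
    """Tune/select/validate one surrogate per metric column.

    Tuning and model choice see only the train and test partitions; the
    validation partition is touched once, by the selected model.
    """
    if "split" not in table:
        raise ValueError("table has no split labels; call dataset.split first")
    space = space or HyperparameterSpace()
    metric_columns = metric_columns or METRIC_COLUMNS
    X_train, train = _partition(table, "train")
    X_test, test = _partition(table, "test")
    X_val, val = _partition(table, "validation")
    if len(train) < 2 or len(test) < 1 or len(val) < 1:
        raise ValueError("every partition must be non-empty (train >= 2 rows)")

    models: Dict[str, SurrogateModel] = {}
    for metric in metric_columns:
        y_train = train[metric].to_numpy(float)
        y_test = test[metric].to_numpy(float)
        candidates = []
        for model_type in MODEL_TYPES:
            params, cv_rmse = tune(model_type, X_train, y_train, space, seed=seed)
            est = fit_model(model_type, params, X_train, y_train, seed=seed)
            test_pred = est.predict(X_test)
            rmse = float(np.sqrt(np.mean((test_pred - y_test) ** 2)))
            candidates.append((rmse, model_type, params, cv_rmse, est, test_pred))
        candidates.sort(key=lambda c: c[0])
        rmse, model_type, params, cv_rmse, est, test_pred = candidates[0]
        test_errors = _error_dict(y_test, test_pred)
        # only now does the winner see validation data
        y_val = val[metric].to_numpy(float)
        val_errors = _error_dict(y_val, est.predict(X_val))
        models[metric] = SurrogateModel(
            metric=metric,
            model_type=model_type,
            params=params,
            estimator=est,
            test_errors=test_errors,
            validation_errors=val_errors,
            cv_rmse=cv_rmse,
            seed=seed,
        )
    return models


def _error_dict(y, yhat) -> Dict[str, float]:
    if len(y) < 2 or np.ptp(y) == 0:
        rmse = float(np.sqrt(np.mean((np.asarray(yhat) - np.asarray(y)) ** 2)))
        return {"rmse": rmse, "rrse": float("nan"), "rmsle": float("nan")}
    rmse, rrse, rmsle = error_metrics(y, yhat)
    return {"rmse": rmse, "rrse": rrse, "rmsle": rmsle}


# --------------------------------------------------------------------------
# prediction
# --------------------------------------------------------------------------


def predict(models: Dict[str, SurrogateModel], x) -> AcquisitionMetrics:
    """Predict the 12-metric vector for one sequence vector (dict or array)."""
    values = predict_batch(models, np.atleast_2d(_to_numeric_row(x)))
    return AcquisitionMetrics(**{m: float(values[m][0]) for m in values})


def predict_batch(models: Dict[str, SurrogateModel], X: np.ndarray) -> Dict[str, np.ndarray]:
    """Column-wise predictions for a (n, 10) numeric input matrix."""
    missing = [f for f in METRIC_COLUMNS if f not in models]
    if missing:
        raise ValueError(f"untrained surrogates for {missing}")
    X = np.asarray(X, dtype=float)
    return {m: np.asarray(models[m].estimator.predict(X), dtype=float) for m in METRIC_COLUMNS}


def _to_numeric_row(x) -> np.ndarray:
    if isinstance(x, dict):
        return np.array([float(x[c]) for c in NUMERIC_COLUMNS])
    arr = np.asarray(x, dtype=float)
    if arr.shape[-1] != len(NUMERIC_COLUMNS):
        raise ValueError(f"expected {len(NUMERIC_COLUMNS)} numeric inputs")
    return arr


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------


def pca(X, columns: Optional[List[str]] = None) -> PCAResult:
    """PCA of standardized columns: per-component std dev and variance shares.

    Constant columns carry no variance and are dropped with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a matrix with at least 2 rows and 2 columns")
    columns = list(columns) if columns is not None else [f"x{i}" for i in range(X.shape[1])]
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(columns, keep) if not k]
        warnings.warn(f"dropping constant columns from PCA: {dropped}", stacklevel=2)
        X = X[:, keep]
        columns = [c for c, k in zip(columns, keep) if k]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    cov = np.cov(Z, rowvar=False)
    eigvals = np.linalg.eigvalsh(cov)[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    proportion = eigvals / eigvals.sum()
    return PCAResult(
        std_deviation=np.sqrt(eigvals),
        proportion=proportion,
        cumulative=np.cumsum(proportion),
        columns=columns,
    )
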