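"""Regression models: standardization, the four configured algorithms,
grid search, and persistence.

All four regressors are fitted on z-score-standardized features (the
scaler statistics come exclusively from the training rows) with fixed
defaults: random forest (200 trees, depth 20, sqrt features, random
state 42), RBF-kernel SVR (C=100, gamma="scale"), gradient boosting
(100 estimators, learning rate 0.1, depth 5) and k-NN (9 neighbors,
distance weighting, Manhattan metric).  Grid search minimizes mean
cross-validated MAPE, breaking ties by the order of the grid
specification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence
import warnings

import joblib
import numpy as np
import pandas as pd
import sklearn
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from gripsense import __version__
from gripsense.errors import DataError, UsageError
from gripsense.features import TARGET_COLUMN, feature_columns, schema_hash

ALGORITHMS = ("random_forest", "svr_rbf", "gradient_boosting", "knn")

_DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "random_forest": {"n_estimators": 200, "max_depth": 20, "max_features": "sqrt"},
    "svr_rbf": {"kernel": "rbf", "C": 100.0, "gamma": "scale"},
    "gradient_boosting": {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 5},
    "knn": {"n_neighbors": 9, "weights": "distance", "metric": "manhattan"},
}

#: default grid-search spaces bracketing the fixed configurations
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {"n_estimators": [100, 200], "max_depth": [10, 20]},
    "svr_rbf": {"C": [10.0, 100.0, 1000.0], "gamma": ["scale", 0.01]},
    "gradient_boosting": {"n_estimators": [100, 200],
                          "learning_rate": [0.05, 0.1], "max_depth": [3, 5]},
    "knn": {"n_neighbors": [5, 9, 15], "weights": ["distance"]},
}


@dataclass(frozen=True)
class ModelConfig:
    algorithm: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    random_state: int = 42

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise UsageError(f"unknown algorithm {self.algorithm!r}; "
                             f"choose from {ALGORITHMS}")

    def effective_hyperparameters(self) -> dict:
        hp = dict(_DEFAULT_HYPERPARAMETERS[self.algorithm])
        hp.update(self.hyperparameters)
        return hp


def default_config(algorithm: str, random_state: int = 42) -> ModelConfig:
    return ModelConfig(algorithm, {}, random_state)


def _build_estimator(config: ModelConfig):
    hp = config.effective_hyperparameters()
    if config.algorithm == "random_forest":
        return RandomForestRegressor(random_state=config.random_state,
                                     n_jobs=1, **hp)
    if config.algorithm == "svr_rbf":
        return SVR(**hp)
    if config.algorithm == "gradient_boosting":
        return GradientBoostingRegressor(random_state=config.random_state, **hp)
    if config.algorithm == "knn":
        return KNeighborsRegressor(n_jobs=1, **hp)
    raise UsageError(config.algorithm)


@dataclass
class FittedModel:
    config: ModelConfig
    pipeline: Pipeline
    feature_names: tuple[str, ...]

    @property
    def schema_hash(self) -> str:
        return schema_hash(self.feature_names)


def _split_xy(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    names = feature_columns(data)
    X = data[names].to_numpy(dtype=float)
    y = data[TARGET_COLUMN].to_numpy(dtype=float)
    return X, y, names


def fit(config: ModelConfig, train: pd.DataFrame) -> FittedModel:
    """Standardize on the training rows only, then fit the configured regressor."""
    X, y, names = _split_xy(train)
    if X.shape[0] < 2:
        raise UsageError("need at least 2 training rows")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise DataError("training matrix contains missing or non-finite values")
    if np.any(X.std(axis=0) == 0):
        const = [names[j] for j in np.nonzero(X.std(axis=0) == 0)[0]]
        warnings.warn(f"constant feature columns scaled by 1: {const[:5]}"
                      f"{'...' if len(const) > 5 else ''}", stacklevel=2)
    pipe = Pipeline([("scaler", StandardScaler()),
                     ("regressor", _build_estimator(config))])
    pipe.fit(X, y)
    return FittedModel(config, pipe, tuple(names))


def predict(model: FittedModel, rows: pd.DataFrame) -> np.ndarray:
    """Grip estimates in kg, one per row; refuses schema mismatches."""
    names = feature_columns(rows)
    if tuple(names) != model.feature_names:
        raise UsageError(
            f"feature schema mismatch: model was fitted on schema "
            f"{model.schema_hash}, got {schema_hash(names)}")
    X = rows[names].to_numpy(dtype=float)
    return np.asarray(model.pipeline.predict(X), dtype=float)


def grid_search(algorithm: str, grid: Mapping[str, Sequence], data: pd.DataFrame,
                folds: int = 5, random_state: int = 42) -> ModelConfig:
    """Pick the config minimizing mean cross-validated MAPE over the grid.

    Candidates are enumerated in the order of the grid specification
    (itertools.product over the given value lists); the first candidate
    achieving the minimum score wins, which makes ties deterministic.
    """
    from gripsense.evaluation import metrics  # local import avoids a cycle

    if not grid:
        raise UsageError("grid must be nonempty")
    if folds < 2:
        raise UsageError("folds must be >= 2")
    keys = list(grid)
    kf = KFold(n_splits=folds, shuffle=True, random_state=random_state)
    X_index = np.arange(len(data))
    best: tuple[float, ModelConfig] | None = None
    scores: list[tuple[dict, float]] = []
    for values in product(*(grid[k] for k in keys)):
        hp = dict(zip(keys, values))
        config = ModelConfig(algorithm, hp, random_state)
        fold_mapes = []
        try:
            for tr, te in kf.split(X_index):
                model = fit(config, data.iloc[tr])
                pred = predict(model, data.iloc[te])
                mae, mape, r2 = metrics(
                    data.iloc[te][TARGET_COLUMN].to_numpy(), pred)
                fold_mapes.append(mape)
        except Exception as e:  # candidate failed; skip with a warning
            warnings.warn(f"grid candidate {hp} failed: {e}", stacklevel=2)
            continue
        score = float(np.mean(fold_mapes))
        scores.append((hp, score))
        if best is None or score < best[0]:
            best = (score, config)
    if best is None:
        raise DataError("every grid candidate failed to fit")
    return best[1]


# -- persistence --------------------------------------------------------------

ARCHIVE_VERSION = 1


def save_model(model: FittedModel, path: str | Path) -> None:
    """Persist a fitted model with enough metadata to refuse stale loads."""
    joblib.dump({
        "archive_version": ARCHIVE_VERSION,
        "gripsense_version": __version__,
        "sklearn_version": sklearn.__version__,
        "config": {"algorithm": model.config.algorithm,
                   "hyperparameters": dict(model.config.hyperparameters),
                   "random_state": model.config.random_state},
        "feature_names": list(model.feature_names),
        "schema_hash": model.schema_hash,
        "pipeline": model.pipeline,
    }, path)


def load_model(path: str | Path) -> FittedModel:
    obj = joblib.load(path)
    if obj.get("archive_version") != ARCHIVE_VERSION:
        raise UsageError(f"unsupported model archive version "
                         f"{obj.get('archive_version')!r}")
    if obj.get("sklearn_version") != sklearn.__version__:
        raise UsageError(
            f"model archive was written with scikit-learn "
            f"{obj.get('sklearn_version')}, running {sklearn.__version__}")
    cfg = obj["config"]
    return FittedModel(ModelConfig(cfg["algorithm"], cfg["hyperparameters"],
                                   cfg["random_state"]),
                       obj["pipeline"], tuple(obj["feature_names"]))


def run_manifest(model: FittedModel) -> dict:
    """Effective hyperparameters and library versions for reproducibility logs."""
    reg = model.pipeline.named_steps["regressor"]
    return {
        "algorithm": model.config.algorithm,
        "effective_hyperparameters": {
            k: v for k, v in sorted(reg.get_params().items())
            if not k.startswith("estimator")},
        "schema_hash": model.schema_hash,
        "n_features": len(model.feature_names),
        "gripsense_version": __version__,
        "sklearn_version": sklearn.__version__,
    }
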