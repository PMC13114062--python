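"""Classifier training with subject-grouped grid search.

Five standard learners — decision tree, k-nearest neighbours, random
forest, RBF support-vector machine, and XGBoost — each tuned over a
small hyperparameter grid by mean accuracy on subject-grouped inner CV
folds, then refit on all training rows.  Distance-based models (KNN,
SVM) are z-scored with statistics learned from the training rows only;
tree ensembles consume raw features.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .cv import fold_epoch_indices, subject_folds
from .errors import ConfigError, DataError

__all__ = ["ModelSpec", "FittedModel", "default_specs", "fit_tuned", "MODEL_NAMES"]

MODEL_NAMES = ("DT", "KNN", "RF", "SVM", "XGBoost")

_DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "DT": {"max_depth": [3, 5, 10, None]},
    "KNN": {"n_neighbors": [3, 5, 7, 9]},
    "RF": {"n_estimators": [100, 300], "max_depth": [None, 10]},
    "SVM": {"C": [0.1, 1.0, 10.0]},
    "XGBoost": {"n_estimators": [100, 300], "max_depth": [3, 5],
                "learning_rate": [0.05, 0.1]},
}

#: models whose features are z-scored inside the fitted pipeline
_STANDARDIZED = {"KNN", "SVM"}


@dataclass
class ModelSpec:
    """One classifier family plus its tuning grid."""

    name: str
    grid: dict[str, list] = field(default_factory=dict)
    tuning_folds: int = 3
    seed: int = 0
    standardize: bool | None = None  # None = per-model default

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ConfigError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")
        if not self.grid:
            self.grid = {k: list(v) for k, v in _DEFAULT_GRIDS[self.name].items()}
        if self.standardize is None:
            self.standardize = self.name in _STANDARDIZED


def default_specs(seed: int = 0, names: tuple[str, ...] = MODEL_NAMES,
                  tuning_folds: int = 3) -> list[ModelSpec]:
    return [ModelSpec(name=n, seed=seed, tuning_folds=tuning_folds) for n in names]


def _build(name: str, params: dict, seed: int):
    seed = seed % (2**31)
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed, **params)
    if name == "KNN":
        return KNeighborsClassifier(**params)
    if name == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if name == "SVM":
        return SVC(kernel="rbf", random_state=seed, **params)
    if name == "XGBoost":
        return XGBClassifier(random_state=seed, n_jobs=1, eval_metric="logloss",
                             verbosity=0, **params)
    raise ConfigError(f"unknown model {name!r}")


@dataclass
class FittedModel:
    """A tuned, fitted classifier with its training schema."""

    spec: ModelSpec
    params: dict
    pipeline: Pipeline
    n_features: int
    inner_cv_accuracy: float

    def hyperparameters_json(self) -> str:
        """Portable record of the model family and chosen grid point."""
        import json

        return json.dumps({"model": self.spec.name, "params": self.params,
                           "inner_cv_accuracy": self.inner_cv_accuracy,
                           "standardized": bool(self.spec.standardize)},
                          default=str)

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Hard labels and continuous class-1 scores, same row order."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise DataError(
                f"expected {self.n_features} feature columns, got "
                f"{X.shape[1] if X.ndim == 2 else 'non-2D'}"
            )
        labels = self.pipeline.predict(X)
        est = self.pipeline.named_steps["model"]
        if hasattr(est, "predict_proba") and est.__class__.__name__ != "SVC":
            scores = self.pipeline.predict_proba(X)[:, 1]
        elif hasattr(est, "decision_function"):
            scores = self.pipeline.decision_function(X)
        else:  # pragma: no cover - every supported model has one of the two
            scores = labels.astype(float)
        return np.asarray(labels), np.asarray(scores, dtype=float)


def _grid_points(grid: dict[str, list]):
    keys = list(grid)
    for combo in itertools.product(*(grid[k] for k in keys)):
        yield dict(zip(keys, combo))


def fit_tuned(X: np.ndarray, y: np.ndarray, subject_ids: np.ndarray,
              spec: ModelSpec) -> FittedModel:
    """Grid-search ``spec`` by subject-grouped inner CV accuracy, refit
    the winning configuration on all training rows.

    Ties between grid points keep the earlier point (deterministic
    iteration order).  Standardization statistics are computed inside
    each inner training split and, for the final model, on the full
    training set — never on data outside it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[1] == 0:
        raise DataError("feature matrix must be 2-D with at least one column")
    if not np.all(np.isfinite(X)):
        raise DataError("non-finite feature values")
    if np.unique(y).size < 2:
        raise DataError("training labels contain a single class")
    subject_ids = np.asarray(subject_ids)
    n_subjects = np.unique(subject_ids).size
    k = min(spec.tuning_folds, n_subjects)

    def make_pipeline(params: dict) -> Pipeline:
        steps = []
        if spec.standardize:
            steps.append(("scale", StandardScaler()))
        steps.append(("model", _build(spec.name, params, spec.seed)))
        return Pipeline(steps)

    best_params, best_acc = None, -np.inf
    if k >= 2:
        folds = subject_folds(subject_ids, y, k, seed=spec.seed)
        splits = [fold_epoch_indices(subject_ids, f) for f in folds]
        for params in _grid_points(spec.grid):
            accs = []
            for tr, te in splits:
                if np.unique(y[tr]).size < 2:
                    continue
                pipe = make_pipeline(params)
                pipe.fit(X[tr], y[tr])
                accs.append(accuracy_score(y[te], pipe.predict(X[te])))
            acc = float(np.mean(accs)) if accs else -np.inf
            if acc > best_acc:
                best_params, best_acc = params, acc
    if best_params is None:  # single grid point or too few subjects to tune
        best_params = next(_grid_points(spec.grid))
        best_acc = float("nan")

    final = make_pipeline(best_params)
    final.fit(X, y)
    return FittedModel(spec=spec, params=best_params, pipeline=final,
                       n_features=X.shape[1], inner_cv_accuracy=best_acc)
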