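"""Baseline feature selectors: ant colony optimization, L1-penalized
logistic regression (LASSO), and PCA.

These exist for head-to-head comparison with the RankSearch+GA selector
under identical conditions: ACO and LASSO are steered to pick a subset
of comparable size, and PCA keeps a matching number of components (its
result is a transform, not a named-feature subset).
"""

from __future__ import annotations

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .containers import FeatureMatrix
from .errors import DataError
from .selection import GAConfig, SelectionResult, make_fitness

__all__ = ["aco_select", "lasso_select", "pca_reduce"]


def aco_select(features: FeatureMatrix, target_size: int,
               fitness_config: GAConfig, n_ants: int = 20, n_iters: int = 20,
               evaporation: float = 0.2, seed: int = 0) -> SelectionResult:
    """Binary ant-colony feature selection with a fixed subset size.

    Each ant samples ``target_size`` features without replacement with
    probability proportional to pheromone; subsets are scored with the
    same wrapper fitness as the GA; the iteration-best ant deposits its
    fitness on its features after evaporation.
    """
    d = features.n_features
    if not 1 <= target_size <= d:
        raise DataError(f"target_size must be in [1, {d}]")
    rng = np.random.default_rng(seed)
    fitness = make_fitness(features, fitness_config)
    pheromone = np.ones(d)
    best_mask, best_fit = None, -np.inf
    history = []
    for _ in range(n_iters):
        iter_best_mask, iter_best_fit = None, -np.inf
        for _ in range(n_ants):
            p = pheromone / pheromone.sum()
            chosen = rng.choice(d, size=target_size, replace=False, p=p)
            mask = np.zeros(d, dtype=bool)
            mask[chosen] = True
            f = fitness(mask)
            if f > iter_best_fit:
                iter_best_mask, iter_best_fit = mask, f
        pheromone *= 1.0 - evaporation
        pheromone[iter_best_mask] += max(iter_best_fit, 0.0)
        pheromone = np.clip(pheromone, 1e-6, None)
        if iter_best_fit > best_fit:
            best_mask, best_fit = iter_best_mask, iter_best_fit
        history.append(best_fit)
    selected = np.where(best_mask)[0]
    return SelectionResult(
        method="ACO",
        selected_indices=selected,
        selected_names=[features.feature_names[i] for i in selected],
        best_fitness_history=history,
        best_size_history=[target_size] * len(history),
        mean_size_history=[float(target_size)] * len(history),
        seed=seed,
        n_candidates=d,
        config_echo={"n_ants": n_ants, "n_iters": n_iters,
                     "evaporation": evaporation, "target_size": target_size},
    )


def lasso_select(features: FeatureMatrix, target_size: int | None = None,
                 C: float | None = None, seed: int = 0) -> SelectionResult:
    """L1-penalized logistic regression selection.

    Either fix the inverse penalty ``C`` directly, or give a
    ``target_size`` and the penalty is chosen from a log-spaced path as
    the value whose nonzero-coefficient count is closest to the target.
    With a vanishing penalty (huge C) every feature survives.
    """
    if (target_size is None) == (C is None):
        raise DataError("give exactly one of target_size or C")
    X = StandardScaler().fit_transform(features.values)
    y = features.labels

    def nonzero_mask(c: float) -> np.ndarray:
        clf = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=c,
                                 random_state=seed % (2**31), max_iter=2000)
        clf.fit(X, y)
        return np.abs(clf.coef_[0]) > 1e-10

    if C is not None:
        mask = nonzero_mask(C)
        chosen_c = C
    else:
        grid = np.logspace(-4, 3, 40)
        best_gap, mask, chosen_c = None, None, None
        for c in grid:
            m = nonzero_mask(c)
            gap = abs(int(m.sum()) - target_size)
            if best_gap is None or gap < best_gap:
                best_gap, mask, chosen_c = gap, m, c
            if gap == 0:
                break
    selected = np.where(mask)[0]
    return SelectionResult(
        method="LASSO",
        selected_indices=selected,
        selected_names=[features.feature_names[i] for i in selected],
        seed=seed,
        n_candidates=features.n_features,
        config_echo={"C": float(chosen_c), "target_size": target_size},
    )


def pca_reduce(features: FeatureMatrix, k: int, seed: int = 0) -> SelectionResult:
    """Top-k principal components (standardized inputs).

    The result is a fitted transform rather than a named-feature subset;
    downstream evaluation applies it to train and test alike (fit on
    training rows only).
    """
    if not 1 <= k <= features.n_features:
        raise DataError(f"k must be in [1, {features.n_features}]")
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("pca", PCA(n_components=k, random_state=seed % (2**31))),
    ])
    pipe.fit(features.values)
    return SelectionResult(
        method="PCA",
        selected_indices=np.arange(k),
        selected_names=[f"PC{i + 1}" for i in range(k)],
        seed=seed,
        n_candidates=features.n_features,
        transformer=pipe,
        config_echo={"k": k},
    )
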