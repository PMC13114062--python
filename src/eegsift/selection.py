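"""Two-stage feature selection: mutual-information RankSearch followed by
a ranking-guided genetic algorithm.

Stage 1 (RankSearch) scores every feature by its mutual information with
the class label, sorts descending, and keeps the shortest prefix whose
cumulative share of the total MI reaches a threshold (default 95%).

Stage 2 runs a wrapper genetic algorithm over binary masks of the
retained candidates.  The ranking guides initialization: a candidate's
probability of being switched on in the initial population is affine in
its normalized MI score.  Fitness is the subject-grouped k-fold CV
accuracy of a fixed random forest on the masked columns, minus a small
parsimony penalty proportional to the fraction of features used.
Tournament selection, uniform crossover, per-gene bit-flip mutation and
a one-individual hall of fame complete the loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import mutual_info_classif
from sklearn.metrics import accuracy_score

from .containers import FeatureMatrix
from .cv import fold_epoch_indices, subject_folds
from .errors import ConfigError, DataError

__all__ = [
    "RankingResult",
    "GAConfig",
    "SelectionResult",
    "mutual_information",
    "mi_scores",
    "retained_prefix_count",
    "rank_search",
    "ga_select",
    "make_fitness",
]


# ---------------------------------------------------------------------------
# mutual information


def _discrete_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in MI (nats) from the empirical joint distribution."""
    xs, xi = np.unique(x, return_inverse=True)
    ys, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((len(xs), len(ys)))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz])))


def mutual_information(feature: np.ndarray, labels: np.ndarray, k: int = 3,
                       seed: int = 0, discrete_threshold: int = 10) -> float:
    """MI (nats) between one feature and the binary labels.

    Continuous features use the k-nearest-neighbour estimator (k=3);
    features with at most ``discrete_threshold`` distinct values are
    treated as discrete and scored by the plug-in estimator.  Estimates
    are clipped at zero.
    """
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels)
    if feature.shape[0] != labels.shape[0]:
        raise DataError("feature and label lengths differ")
    if feature.shape[0] < 10:
        raise DataError("need at least 10 samples for an MI estimate")
    if np.unique(feature).size <= 1:
        return 0.0
    if np.unique(feature).size <= discrete_threshold:
        return max(_discrete_mi(feature, labels), 0.0)
    val = mutual_info_classif(feature[:, None], labels, n_neighbors=k,
                              random_state=seed % (2**31))[0]
    return float(max(val, 0.0))


def mi_scores(values: np.ndarray, labels: np.ndarray, k: int = 3,
              seed: int = 0) -> np.ndarray:
    """kNN MI estimate per column (nats, clipped at 0)."""
    scores = mutual_info_classif(values, labels, n_neighbors=k,
                                 random_state=seed % (2**31))
    return np.clip(scores, 0.0, None)


# ---------------------------------------------------------------------------
# RankSearch


@dataclass
class RankingResult:
    """Descending-MI feature ranking with cumulative-contribution cut."""

    order: np.ndarray                # feature indices, descending MI
    scores: np.ndarray               # MI per feature, original column order
    cumulative_fraction: np.ndarray  # running share of total MI, ranked order
    retained_mask: np.ndarray        # bool, original column order
    tau: float
    feature_names: list[str]

    @property
    def n_retained(self) -> int:
        return int(self.retained_mask.sum())

    @property
    def retained_indices(self) -> np.ndarray:
        """Retained candidates in rank order (best first)."""
        return self.order[: self.n_retained]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "feature": [self.feature_names[i] for i in self.order],
            "mi": self.scores[self.order],
            "cumulative_fraction": self.cumulative_fraction,
            "retained": [bool(self.retained_mask[i]) for i in self.order],
        })


def retained_prefix_count(sorted_scores: np.ndarray, tau: float) -> int:
    """Length of the shortest prefix of descending scores whose
    cumulative share of the total reaches ``tau``."""
    sorted_scores = np.asarray(sorted_scores, dtype=float)
    total = sorted_scores.sum()
    if total <= 0:
        return len(sorted_scores)
    cum = np.cumsum(sorted_scores) / total
    return int(np.searchsorted(cum, tau - 1e-12) + 1)


def rank_search(features: FeatureMatrix, tau: float = 0.95,
                seed: int = 0) -> RankingResult:
    """Stage-1 filter: keep the shortest descending-MI prefix whose
    cumulative share of total MI reaches ``tau``.

    Ties in MI are broken by original column index (stable sort).  If
    every score is zero (labels carry no information about any feature)
    all features are retained.
    """
    if features.n_features < 2:
        raise DataError("need at least 2 features to rank")
    labels = features.labels
    if np.unique(labels).size < 2:
        raise DataError("labels contain a single class")
    if not 0 < tau <= 1.0:
        raise ConfigError("tau must be in (0, 1]")
    scores = mi_scores(features.values, labels, seed=seed)
    order = np.argsort(-scores, kind="stable")
    total = scores.sum()
    mask = np.zeros(features.n_features, dtype=bool)
    if total <= 0:
        cum = np.ones(features.n_features)
        mask[:] = True
    else:
        cum = np.cumsum(scores[order]) / total
        n_keep = retained_prefix_count(scores[order], tau)
        mask[order[:n_keep]] = True
    return RankingResult(order=order, scores=scores, cumulative_fraction=cum,
                         retained_mask=mask, tau=tau,
                         feature_names=list(features.feature_names))


# ---------------------------------------------------------------------------
# genetic algorithm


@dataclass
class GAConfig:
    """Genetic-algorithm settings.

    Defaults follow common wrapper-selection practice: population 50,
    20 generations, crossover 0.8, per-gene mutation 0.05, one-elite
    hall of fame, 5-fold subject-grouped random-forest fitness.  The
    parsimony weight adds ``-lambda * (subset size / candidate count)``
    to the fitness so redundant genes are slowly squeezed out; set it to
    0 for pure-accuracy fitness.  ``adaptive_mutation`` optionally decays
    the mutation rate from 2*p_m to p_m/2 across generations.
    """

    population_size: int = 50
    generations: int = 20
    crossover_prob: float = 0.8
    mutation_prob: float = 0.05
    elitism_count: int = 1
    fitness_cv_folds: int = 5
    rf_trees: int = 100
    parsimony_weight: float = 0.01
    init_prob_range: tuple[float, float] = (0.2, 0.8)
    tournament_size: int = 3
    adaptive_mutation: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_prob <= 1 and 0 <= self.mutation_prob <= 1):
            raise ConfigError("probabilities must lie in [0, 1]")
        if self.population_size < 2:
            raise ConfigError("population must be at least 2")
        if self.parsimony_weight < 0:
            raise ConfigError("parsimony weight must be >= 0")
        lo, hi = self.init_prob_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigError("init_prob_range must satisfy 0 <= lo <= hi <= 1")


@dataclass
class SelectionResult:
    """Outcome of a feature-selection run."""

    method: str
    selected_indices: np.ndarray        # into the candidate column space
    selected_names: list[str]
    best_fitness_history: list[float] = field(default_factory=list)
    best_size_history: list[int] = field(default_factory=list)
    mean_size_history: list[float] = field(default_factory=list)
    seed: int = 0
    n_candidates: int = 0
    transformer: object | None = None   # set for PCA-style transforms
    config_echo: dict = field(default_factory=dict)

    @property
    def is_transform(self) -> bool:
        return self.transformer is not None

    def to_json(self) -> str:
        return json.dumps({
            "method": self.method,
            "selected_names": list(self.selected_names),
            "selected_indices": [int(i) for i in self.selected_indices],
            "best_fitness_history": [float(v) for v in self.best_fitness_history],
            "best_size_history": [int(v) for v in self.best_size_history],
            "mean_size_history": [float(v) for v in self.mean_size_history],
            "seed": self.seed,
            "n_candidates": self.n_candidates,
            "config": self.config_echo,
        }, indent=2)


def make_fitness(features: FeatureMatrix,
                 config: GAConfig) -> Callable[[np.ndarray], float]:
    """Build the wrapper fitness: mean subject-grouped CV accuracy of a
    fixed random forest on the masked columns, minus the parsimony term.

    The same fold partition and forest seed are reused for every mask so
    fitness values are comparable across chromosomes; evaluations are
    memoized on the mask bits.
    """
    labels = features.labels
    n_subjects = np.unique(features.subject_ids).size
    k = min(config.fitness_cv_folds, n_subjects)
    if k < 2:
        raise DataError("need at least 2 subjects for wrapper fitness")
    folds = subject_folds(features.subject_ids, labels, k, seed=config.seed)
    splits = [fold_epoch_indices(features.subject_ids, f) for f in folds]
    X = features.values
    d = X.shape[1]
    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        key = np.packbits(mask).tobytes()
        if key in cache:
            return cache[key]
        size = int(mask.sum())
        if size == 0:
            cache[key] = -np.inf
            return -np.inf
        accs = []
        for tr, te in splits:
            clf = RandomForestClassifier(
                n_estimators=config.rf_trees,
                random_state=config.seed % (2**31),
                n_jobs=1,
            )
            clf.fit(X[np.ix_(tr, np.where(mask)[0])], labels[tr])
            pred = clf.predict(X[np.ix_(te, np.where(mask)[0])])
            accs.append(accuracy_score(labels[te], pred))
        val = float(np.mean(accs)) - config.parsimony_weight * (size / d)
        cache[key] = val
        return val

    return fitness


def _repair(mask: np.ndarray, top_gene: int) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[top_gene] = True
    return mask


def _tournament(rng: np.random.Generator, fitnesses: np.ndarray,
                size: int) -> int:
    contenders = rng.integers(0, len(fitnesses), size=size)
    return int(contenders[np.argmax(fitnesses[contenders])])


def ga_select(features: FeatureMatrix, ranking_scores: np.ndarray | None,
              config: GAConfig) -> SelectionResult:
    """Stage-2 wrapper GA over the candidate features in ``features``.

    ``ranking_scores`` are the MI scores of the candidate columns (same
    order); they bias initialization — the inclusion probability of gene
    j is affine in its normalized MI within ``init_prob_range`` — and
    name the gene used to repair empty chromosomes.  Pass ``None`` for
    unbiased initialization at the midpoint probability.

    Histories have length generations+1 (initial population included);
    elitism makes the best-fitness history non-decreasing.
    """
    d = features.n_features
    if d < 2:
        raise DataError("need at least 2 candidate features")
    if np.unique(features.labels).size < 2:
        raise DataError("labels contain a single class")
    rng = np.random.default_rng(config.seed)
    fitness = make_fitness(features, config)

    p_lo, p_hi = config.init_prob_range
    if ranking_scores is None:
        p_init = np.full(d, (p_lo + p_hi) / 2.0)
        top_gene = 0
    else:
        s = np.asarray(ranking_scores, dtype=float)
        if s.shape[0] != d:
            raise DataError("ranking_scores length must match candidate count")
        span = s.max() - s.min()
        norm = (s - s.min()) / span if span > 0 else np.full(d, 0.5)
        p_init = p_lo + (p_hi - p_lo) * norm
        top_gene = int(np.argmax(s))

    pop = rng.random((config.population_size, d)) < p_init
    pop = np.array([_repair(ind, top_gene) for ind in pop])
    fits = np.array([fitness(ind) for ind in pop])
    elite_idx = int(np.argmax(fits))
    elite, elite_fit = pop[elite_idx].copy(), float(fits[elite_idx])

    best_fitness_history = [elite_fit]
    best_size_history = [int(elite.sum())]
    mean_size_history = [float(pop.sum(axis=1).mean())]

    for gen in range(config.generations):
        if config.adaptive_mutation and config.generations > 1:
            frac = gen / (config.generations - 1)
            p_m = (2.0 - 1.5 * frac) * config.mutation_prob  # 2*p_m -> p_m/2
        else:
            p_m = config.mutation_prob
        offspring = []
        n_off = config.population_size - config.elitism_count
        while len(offspring) < n_off:
            i1 = _tournament(rng, fits, config.tournament_size)
            i2 = _tournament(rng, fits, config.tournament_size)
            c1, c2 = pop[i1].copy(), pop[i2].copy()
            if rng.random() < config.crossover_prob:
                swap = rng.random(d) < 0.5
                c1[swap], c2[swap] = pop[i2][swap], pop[i1][swap]
            for child in (c1, c2):
                flips = rng.random(d) < p_m
                child ^= flips
                offspring.append(_repair(child, top_gene))
                if len(offspring) == n_off:
                    break
        pop = np.array([elite.copy()] * config.elitism_count + offspring)
        fits = np.array([fitness(ind) for ind in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > elite_fit:
            elite, elite_fit = pop[gen_best].copy(), float(fits[gen_best])
        best_fitness_history.append(elite_fit)
        best_size_history.append(int(elite.sum()))
        mean_size_history.append(float(pop.sum(axis=1).mean()))

    selected = np.where(elite)[0]
    return SelectionResult(
        method="RS+GA",
        selected_indices=selected,
        selected_names=[features.feature_names[i] for i in selected],
        best_fitness_history=best_fitness_history,
        best_size_history=best_size_history,
        mean_size_history=mean_size_history,
        seed=config.seed,
        n_candidates=d,
        config_echo={"population_size": config.population_size,
                     "generations": config.generations,
                     "crossover_prob": config.crossover_prob,
                     "mutation_prob": config.mutation_prob,
                     "parsimony_weight": config.parsimony_weight},
    )
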