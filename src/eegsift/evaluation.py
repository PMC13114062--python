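"""Subject-level cross-validated evaluation.

Per outer fold the *entire* selection stage (MI ranking, GA) is re-run
on the training subjects only, each classifier is tuned and fitted on
the selected columns, and epoch-level predictions on the held-out
subjects are scored with six metrics: accuracy, sensitivity,
specificity, F1, Cohen's kappa and AUC.  Selected subsets are compared
across folds with Jaccard similarity to quantify selection stability.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .baselines import aco_select, lasso_select, pca_reduce
from .containers import FeatureMatrix
from .cv import fold_epoch_indices, subject_folds
from .errors import ConfigError, DataError
from .modeling import FittedModel, ModelSpec, fit_tuned
from .selection import (GAConfig, SelectionResult, ga_select, mi_scores,
                        mutual_information, rank_search)

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "CVReport",
    "confusion_counts",
    "roc_points",
    "auc_trapezoid",
    "compute_metrics",
    "jaccard_stability",
    "group_feature_stats",
    "run_cv",
    "duration_sweep",
    "subject_folds",
]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def roc_points(y_true: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC by threshold sweep over the unique scores.

    Returns (fpr, tpr), starting at (0, 0) and ending at (1, 1); tied
    scores share a single operating point.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    y = y_true[order]
    s = scores[order]
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError("ROC needs both classes present")
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # keep only the last index of each tied-score run
    distinct = np.r_[np.where(np.diff(s))[0], len(s) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return fpr, tpr


def auc_trapezoid(y_true: np.ndarray, scores: np.ndarray) -> float:
    fpr, tpr = roc_points(y_true, scores)
    return float(np.trapezoid(tpr, fpr))


@dataclass
class MetricSet:
    """The six evaluation metrics of one prediction set.

    kappa's chance agreement p_e is the class-marginal product form:
    sum over classes of (actual count * predicted count) / n^2.
    Metrics whose denominator is empty (e.g. sensitivity with no
    positives) are NaN and flagged in ``undefined``.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    kappa: float
    auc: float
    p_o: float = float("nan")
    p_e: float = float("nan")
    roc: tuple | None = None
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "f1": self.f1,
                "kappa": self.kappa, "auc": self.auc}


METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "f1", "kappa", "auc")


def compute_metrics(counts: ConfusionCounts, scores: np.ndarray | None = None,
                    y_true: np.ndarray | None = None) -> MetricSet:
    """Evaluate the six metrics from confusion counts (and, for AUC,
    the continuous scores with their true labels)."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    n = counts.n
    if n == 0:
        raise DataError("empty confusion counts")
    undefined: list[str] = []
    accuracy = (tp + tn) / n
    if tp + fn > 0:
        sensitivity = tp / (tp + fn)
    else:
        sensitivity = float("nan")
        undefined.append("sensitivity")
    if tn + fp > 0:
        specificity = tn / (tn + fp)
    else:
        specificity = float("nan")
        undefined.append("specificity")
    if 2 * tp + fp + fn > 0:
        f1 = 2 * tp / (2 * tp + fp + fn)
    else:
        f1 = float("nan")
        undefined.append("f1")
    p_o = accuracy
    p_e = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n**2
    if p_e < 1.0:
        kappa = (p_o - p_e) / (1.0 - p_e)
    else:
        kappa = float("nan")
        undefined.append("kappa")
    roc = None
    auc = float("nan")
    if scores is not None and y_true is not None:
        try:
            fpr, tpr = roc_points(y_true, scores)
            roc = (fpr, tpr)
            auc = float(np.trapezoid(tpr, fpr))
        except DataError:
            undefined.append("auc")
    else:
        undefined.append("auc")
    return MetricSet(accuracy=accuracy, sensitivity=sensitivity,
                     specificity=specificity, f1=f1, kappa=kappa, auc=auc,
                     p_o=p_o, p_e=p_e, roc=roc, undefined=undefined)


def jaccard_stability(subsets: list[set] | list[list]) -> tuple[np.ndarray, float]:
    """Pairwise Jaccard matrix of fold subsets and its mean off-diagonal.

    J(A, B) = |A n B| / |A u B|; two empty sets count as identical (1),
    one empty set against a non-empty one as disjoint (0).
    """
    sets = [set(s) for s in subsets]
    if len(sets) < 2:
        raise DataError("need at least 2 subsets")
    k = len(sets)
    mat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            union = sets[i] | sets[j]
            if not union:
                val = 1.0
            else:
                val = len(sets[i] & sets[j]) / len(union)
            mat[i, j] = mat[j, i] = val
    off = mat[~np.eye(k, dtype=bool)]
    return mat, float(off.mean())


def group_feature_stats(features: FeatureMatrix, seed: int = 0) -> pd.DataFrame:
    """Per-feature Welch t statistic (positive when the control/class-0
    mean exceeds the patient/class-1 mean) plus the MI score.

    Zero-variance features get NaN t values and a ``degenerate`` flag.
    """
    y = features.labels
    if np.sum(y == 0) < 2 or np.sum(y == 1) < 2:
        raise DataError("need at least 2 epochs per class")
    x0 = features.values[y == 0]
    x1 = features.values[y == 1]
    mis = mi_scores(features.values, y, seed=seed)
    rows = []
    for j, name in enumerate(features.feature_names):
        degenerate = x0[:, j].std() == 0 and x1[:, j].std() == 0
        if degenerate:
            t = float("nan")
            p = float("nan")
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t, p = stats.ttest_ind(x0[:, j], x1[:, j], equal_var=False)
        rows.append({"feature": name, "t": float(t), "p": float(p),
                     "mi": float(mis[j]), "degenerate": degenerate})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-validated pipeline


@dataclass
class FoldResult:
    fold: int
    test_subjects: list[str]
    selection: SelectionResult
    per_model: dict[str, MetricSet]
    counts: dict[str, ConfusionCounts]
    flagged: bool = False


@dataclass
class CVReport:
    """Everything produced by one cross-validated run."""

    folds: list[FoldResult]
    selector: str
    k: int
    seed: int
    jaccard_matrix: np.ndarray | None = None
    jaccard_mean: float | None = None

    def aggregate(self) -> pd.DataFrame:
        """Mean +- sd of each metric per model over folds (NaN-aware:
        undefined fold metrics are excluded, with the exclusion count)."""
        rows = []
        models = list(self.folds[0].per_model)
        for m in models:
            for metric in METRIC_NAMES:
                vals = np.array([getattr(f.per_model[m], metric) for f in self.folds])
                ok = np.isfinite(vals)
                rows.append({
                    "model": m, "metric": metric,
                    "mean": float(np.mean(vals[ok])) if ok.any() else float("nan"),
                    "sd": float(np.std(vals[ok])) if ok.any() else float("nan"),
                    "n_folds": int(ok.sum()),
                    "n_excluded": int((~ok).sum()),
                })
        return pd.DataFrame(rows)

    def mean_metric(self, model: str, metric: str = "accuracy") -> float:
        vals = np.array([getattr(f.per_model[model], metric) for f in self.folds])
        ok = np.isfinite(vals)
        return float(np.mean(vals[ok])) if ok.any() else float("nan")

    def best_model(self, metric: str = "accuracy") -> tuple[str, float]:
        models = list(self.folds[0].per_model)
        means = {m: self.mean_metric(m, metric) for m in models}
        best = max(means, key=lambda m: means[m])
        return best, means[best]

    def to_flat_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            for m, ms in f.per_model.items():
                for metric in METRIC_NAMES:
                    rows.append({"fold": f.fold, "model": m, "metric": metric,
                                 "value": getattr(ms, metric)})
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "selector": self.selector, "k": self.k, "seed": self.seed,
            "jaccard_mean": self.jaccard_mean,
            "aggregate": self.aggregate().to_dict(orient="records"),
            "folds": [{
                "fold": f.fold,
                "test_subjects": [str(s) for s in f.test_subjects],
                "selected": list(f.selection.selected_names),
                "metrics": {m: ms.as_dict() for m, ms in f.per_model.items()},
            } for f in self.folds],
        }
        return json.dumps(payload, indent=2, default=float)


def _select_on_train(train_fm: FeatureMatrix, selector: str, tau: float,
                     ga_config: GAConfig, seed: int,
                     target_size: int | None) -> tuple[SelectionResult, object]:
    """Run the configured selector on training data only.

    Returns the SelectionResult plus a column-picker: either an index
    array into the full feature space or a fitted transform.
    """
    if selector == "none":
        idx = np.arange(train_fm.n_features)
        res = SelectionResult(method="none", selected_indices=idx,
                              selected_names=list(train_fm.feature_names),
                              n_candidates=train_fm.n_features)
        return res, idx
    ranking = rank_search(train_fm, tau=tau, seed=seed)
    cand_idx = ranking.retained_indices
    if selector == "rank":
        res = SelectionResult(method="RankSearch",
                              selected_indices=cand_idx,
                              selected_names=[train_fm.feature_names[i]
                                              for i in cand_idx],
                              seed=seed, n_candidates=train_fm.n_features)
        return res, cand_idx
    if selector == "rs+ga":
        cand_fm = train_fm.select_columns(cand_idx)
        res = ga_select(cand_fm, ranking.scores[cand_idx], ga_config)
        return res, cand_idx[res.selected_indices]
    # size-matched baselines: target defaults to half the candidates
    size = target_size or max(1, len(cand_idx) // 2)
    if selector == "aco":
        res = aco_select(train_fm, size, ga_config, seed=seed)
        return res, res.selected_indices
    if selector == "lasso":
        res = lasso_select(train_fm, target_size=size, seed=seed)
        return res, res.selected_indices
    if selector == "pca":
        res = pca_reduce(train_fm, size, seed=seed)
        return res, res.transformer
    raise ConfigError(f"unknown selector {selector!r}")


def run_cv(features: FeatureMatrix, models: list[ModelSpec], k: int = 10,
           seed: int = 0, selector: str = "rs+ga", tau: float = 0.95,
           ga_config: GAConfig | None = None,
           target_size: int | None = None) -> CVReport:
    """Subject-level stratified k-fold CV with per-fold re-selection.

    Every fold: (1) split subjects; (2) run the selector on training
    epochs only; (3) tune and fit each model on the selected training
    columns; (4) score epoch-level predictions on the held-out subjects.
    A fold whose test set contains a single class is flagged and its
    undefined metrics are excluded from aggregates.
    """
    ga_config = ga_config or GAConfig(seed=seed)
    folds = subject_folds(features.subject_ids, features.labels, k, seed=seed)
    results: list[FoldResult] = []
    subsets: list[set] = []
    for fi, test_subjects in enumerate(folds):
        tr_idx, te_idx = fold_epoch_indices(features.subject_ids, test_subjects)
        assert not set(features.subject_ids[tr_idx]) & set(features.subject_ids[te_idx])
        train_fm = features.select_rows(tr_idx)
        fold_seed = (seed + 1009 * (fi + 1)) % (2**31)
        fold_ga = GAConfig(**{**ga_config.__dict__, "seed": fold_seed})
        sel, picker = _select_on_train(train_fm, selector, tau, fold_ga,
                                       fold_seed, target_size)
        if isinstance(picker, np.ndarray):
            Xtr = train_fm.values[:, picker]
            Xte = features.values[np.ix_(te_idx, picker)]
        else:  # fitted transform (PCA)
            Xtr = picker.transform(train_fm.values)
            Xte = picker.transform(features.values[te_idx])
        y_tr = train_fm.labels
        y_te = features.labels[te_idx]
        per_model: dict[str, MetricSet] = {}
        counts: dict[str, ConfusionCounts] = {}
        flagged = np.unique(y_te).size < 2
        for spec in models:
            fold_spec = ModelSpec(name=spec.name, grid=spec.grid,
                                  tuning_folds=spec.tuning_folds,
                                  seed=fold_seed,
                                  standardize=spec.standardize)
            fitted: FittedModel = fit_tuned(Xtr, y_tr, train_fm.subject_ids,
                                            fold_spec)
            pred, scores = fitted.predict(Xte)
            cc = confusion_counts(y_te, pred)
            counts[spec.name] = cc
            per_model[spec.name] = compute_metrics(cc, scores, y_te)
        subsets.append(set(sel.selected_names))
        results.append(FoldResult(fold=fi, test_subjects=[str(s) for s in
                                                          test_subjects],
                                  selection=sel, per_model=per_model,
                                  counts=counts, flagged=flagged))
    jac_mat, jac_mean = (None, None)
    if len(subsets) >= 2 and selector != "none":
        jac_mat, jac_mean = jaccard_stability(subsets)
    return CVReport(folds=results, selector=selector, k=k, seed=seed,
                    jaccard_matrix=jac_mat, jaccard_mean=jac_mean)


def duration_sweep(recordings, minutes: list[float], models: list[ModelSpec],
                   k: int = 10, seed: int = 0, selector: str = "rank",
                   tau: float = 0.95, ga_config: GAConfig | None = None,
                   preprocess_kwargs: dict | None = None,
                   feature_config=None) -> pd.DataFrame:
    """Accuracy per recording duration per model.

    Recordings are truncated to each requested duration *before*
    segmentation, then the full preprocess -> extract -> CV pipeline is
    repeated.  Truncation to the full length reproduces the untruncated
    run exactly.
    """
    from .pipeline import extract_cohort

    rows = []
    for mins in minutes:
        secs = mins * 60.0
        truncated = []
        for rec in recordings:
            n = int(round(secs * rec.fs))
            if n > rec.n_samples:
                raise DataError(
                    f"requested {mins} min exceeds recording "
                    f"{rec.subject_id} ({rec.duration_s:.1f}s)")
            truncated.append(rec.with_samples(rec.samples[:, :n]))
        fm = extract_cohort(truncated, feature_config=feature_config,
                            **(preprocess_kwargs or {}))
        report = run_cv(fm, models, k=k, seed=seed, selector=selector,
                        tau=tau, ga_config=ga_config)
        for spec in models:
            rows.append({"minutes": mins, "model": spec.name,
                         "accuracy": report.mean_metric(spec.name, "accuracy"),
                         "auc": report.mean_metric(spec.name, "auc")})
    return pd.DataFrame(rows)
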