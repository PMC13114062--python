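"""Metrics arithmetic, fold construction, stability, CV pipeline."""

import numpy as np
import pytest

from conftest import planted_feature_matrix
from eegsift.containers import FeatureMatrix
from eegsift.errors import DataError
from eegsift.evaluation import (ConfusionCounts, auc_trapezoid,
                                compute_metrics, confusion_counts,
                                duration_sweep, group_feature_stats,
                                jaccard_stability, roc_points, run_cv)
from eegsift.cv import fold_epoch_indices, subject_folds
from eegsift.modeling import ModelSpec
from eegsift.selection import GAConfig
from oracles import auc_pair_count


class TestSubjectFolds:
    def test_husm_sized_cohort_folds(self):
        """64 subjects (34 pos / 30 neg), k=10: folds of 6-7 subjects,
        each containing both classes, all disjoint."""
        sids = np.array([f"p{i}" for i in range(34)] +
                        [f"n{i}" for i in range(30)])
        labels = np.r_[np.ones(34, int), np.zeros(30, int)]
        folds = subject_folds(sids, labels, 10, seed=0)
        sizes = [len(f) for f in folds]
        assert all(6 <= s <= 7 for s in sizes)
        assert sum(sizes) == 64
        all_subjects = np.concatenate(folds)
        assert len(set(all_subjects)) == 64
        lab = dict(zip(sids, labels))
        for f in folds:
            classes = {lab[s] for s in f}
            assert classes == {0, 1}

    def test_leave_one_subject_out_limit(self):
        sids = np.array([f"s{i}" for i in range(8)])
        labels = np.resize([0, 1], 8)
        folds = subject_folds(sids, labels, 8, seed=1)
        assert all(len(f) == 1 for f in folds)

    def test_same_seed_same_partition(self):
        sids = np.repeat([f"s{i}" for i in range(12)], 3)
        labels = np.repeat(np.resize([0, 1], 12), 3)
        f1 = subject_folds(sids, labels, 4, seed=7)
        f2 = subject_folds(sids, labels, 4, seed=7)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(np.sort(a), np.sort(b))

    def test_more_folds_than_subjects_rejected(self):
        with pytest.raises(DataError):
            subject_folds(np.array(["a", "b"]), np.array([0, 1]), 3, 0)

    def test_epoch_indices_are_complementary(self):
        sids = np.repeat(["a", "b", "c", "d"], 5)
        labels = np.repeat([0, 1, 0, 1], 5)
        folds = subject_folds(sids, labels, 2, seed=0)
        tr, te = fold_epoch_indices(sids, folds[0])
        assert len(tr) + len(te) == 20
        assert not set(sids[tr]) & set(sids[te])


class TestMetricArithmetic:
    def test_hand_computed_confusion_case(self):
        """TP=45 TN=45 FP=5 FN=5: every metric 0.90, p_e=0.5, kappa=0.8."""
        m = compute_metrics(ConfusionCounts(tp=45, tn=45, fp=5, fn=5))
        assert m.accuracy == pytest.approx(0.90)
        assert m.sensitivity == pytest.approx(0.90)
        assert m.specificity == pytest.approx(0.90)
        assert m.f1 == pytest.approx(0.90)
        assert m.p_e == pytest.approx(0.50)
        assert m.kappa == pytest.approx(0.80)

    def test_perfect_prediction(self):
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        scores = y.astype(float)
        m = compute_metrics(confusion_counts(y, y), scores, y)
        for name in ("accuracy", "sensitivity", "specificity", "f1",
                     "kappa", "auc"):
            assert getattr(m, name) == pytest.approx(1.0)

    def test_four_point_auc_case(self):
        """scores [0.1,0.4,0.35,0.8], labels [0,0,1,1]: 3 of 4
        (pos, neg) pairs concordant -> AUC 0.75."""
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.4, 0.35, 0.8])
        assert auc_trapezoid(y, s) == pytest.approx(0.75)

    def test_auc_equals_mann_whitney_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(10, 40))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert auc_trapezoid(y, s) == pytest.approx(
                auc_pair_count(y, s), abs=1e-12)

    def test_reversed_scores_flip_auc(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.random(50)
        assert auc_trapezoid(y, -s) == pytest.approx(1 - auc_trapezoid(y, s))

    def test_roc_curve_is_valid(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        fpr, tpr = roc_points(y, rng.random(60))
        assert fpr[0] == 0 and tpr[0] == 0
        assert fpr[-1] == 1 and tpr[-1] == 1
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_missing_class_flags_metrics_undefined(self):
        m = compute_metrics(ConfusionCounts(tp=5, tn=0, fp=0, fn=0))
        assert "specificity" in m.undefined
        assert np.isnan(m.specificity)


class TestJaccard:
    def test_textbook_cases(self):
        mat, mean = jaccard_stability([{"a", "b", "c"}, {"b", "c", "d"}])
        assert mat[0, 1] == pytest.approx(0.5)
        assert mean == pytest.approx(0.5)
        assert jaccard_stability([{"a"}, {"a"}])[1] == 1.0
        assert jaccard_stability([{"a"}, {"b"}])[1] == 0.0

    def test_empty_set_conventions(self):
        assert jaccard_stability([set(), set()])[1] == 1.0
        assert jaccard_stability([set(), {"a"}])[1] == 0.0

    def test_matrix_symmetric_unit_diagonal(self):
        mat, _ = jaccard_stability([{"a", "b"}, {"b"}, {"c"}])
        np.testing.assert_allclose(mat, mat.T)
        np.testing.assert_allclose(np.diag(mat), 1.0)


class TestGroupFeatureStats:
    def test_identical_distributions_small_t(self):
        rng = np.random.default_rng(3)
        fm = FeatureMatrix(
            values=rng.standard_normal((200, 40)),
            feature_names=[f"f{i}" for i in range(40)],
            subject_ids=np.array([f"s{i}" for i in range(200)]),
            labels=np.r_[np.zeros(100, int), np.ones(100, int)])
        stats_df = group_feature_stats(fm)
        assert (stats_df["t"].abs() < 3).mean() >= 0.95

    def test_two_sd_shift_gives_large_t(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((200, 1))
        x[100:] += 2.0
        fm = FeatureMatrix(values=x, feature_names=["f0"],
                           subject_ids=np.array([f"s{i}" for i in range(200)]),
                           labels=np.r_[np.zeros(100, int), np.ones(100, int)])
        assert abs(group_feature_stats(fm)["t"].iloc[0]) > 10

    def test_sign_convention_control_minus_patient(self):
        rng = np.random.default_rng(5)
        x = (np.r_[np.full(50, 5.0), np.zeros(50)]
             + 0.1 * rng.standard_normal(100))[:, None]
        fm = FeatureMatrix(values=x, feature_names=["f0"],
                           subject_ids=np.array([f"s{i}" for i in range(100)]),
                           labels=np.r_[np.zeros(50, int), np.ones(50, int)])
        assert group_feature_stats(fm)["t"].iloc[0] > 0  # control mean higher

    def test_label_feature_mi_near_label_entropy(self):
        y = np.resize([0, 1], 200)
        fm = FeatureMatrix(values=y[:, None].astype(float),
                           feature_names=["f0"],
                           subject_ids=np.array([f"s{i}" for i in range(200)]),
                           labels=y)
        assert group_feature_stats(fm)["mi"].iloc[0] == pytest.approx(
            np.log(2), abs=0.05)


def _fast_models(seed=0):
    return [ModelSpec("RF", grid={"n_estimators": [30], "max_depth": [None]},
                      seed=seed)]


class TestRunCV:
    def test_no_subject_in_both_train_and_test(self, planted_fm):
        report = run_cv(planted_fm, _fast_models(), k=5, seed=0,
                        selector="rank")
        seen = []
        for f in report.folds:
            seen.extend(f.test_subjects)
        assert sorted(seen) == sorted(set(planted_fm.subject_ids))

    def test_deterministic_report(self, planted_fm):
        r1 = run_cv(planted_fm, _fast_models(), k=4, seed=3, selector="rank")
        r2 = run_cv(planted_fm, _fast_models(), k=4, seed=3, selector="rank")
        assert r1.to_json() == r2.to_json()

    def test_label_shuffle_drives_all_models_to_chance(self):
        """Permuting labels at the subject level must put every model's
        CV accuracy at chance +- 10 points (no leakage anywhere)."""
        fm = planted_feature_matrix(n_subjects_per_class=20,
                                    epochs_per_subject=10, n_informative=3,
                                    n_noise=7, effect_size=1.5, seed=9)
        rng = np.random.default_rng(11)
        subjects = np.unique(fm.subject_ids)
        perm = dict(zip(subjects, rng.permutation(
            [int(fm.labels[fm.subject_ids == s][0]) for s in subjects])))
        shuffled = FeatureMatrix(
            values=fm.values, feature_names=fm.feature_names,
            subject_ids=fm.subject_ids,
            labels=np.array([perm[s] for s in fm.subject_ids]))
        models = [
            ModelSpec("DT", grid={"max_depth": [5]}),
            ModelSpec("KNN", grid={"n_neighbors": [5]}),
            ModelSpec("RF", grid={"n_estimators": [30], "max_depth": [None]}),
            ModelSpec("SVM", grid={"C": [1.0]}),
            ModelSpec("XGBoost", grid={"n_estimators": [50], "max_depth": [3],
                                       "learning_rate": [0.1]}),
        ]
        report = run_cv(shuffled, models, k=8, seed=13, selector="none")
        for name in ("DT", "KNN", "RF", "SVM", "XGBoost"):
            assert abs(report.mean_metric(name) - 0.5) <= 0.10, name

    def test_jaccard_reported_for_selective_runs(self, planted_fm):
        report = run_cv(planted_fm, _fast_models(), k=4, seed=5,
                        selector="rank")
        assert report.jaccard_matrix is not None
        assert 0.0 <= report.jaccard_mean <= 1.0

    def test_ga_selector_smoke(self, planted_fm):
        ga = GAConfig(population_size=6, generations=2, fitness_cv_folds=3,
                      rf_trees=10, seed=1)
        report = run_cv(planted_fm, _fast_models(), k=3, seed=1,
                        selector="rs+ga", ga_config=ga)
        assert report.mean_metric("RF") > 0.6  # planted effect recoverable
        for f in report.folds:
            assert len(f.selection.selected_names) >= 1

    def test_pca_selector_runs(self, planted_fm):
        report = run_cv(planted_fm, _fast_models(), k=3, seed=2,
                        selector="pca", target_size=5)
        assert np.isfinite(report.mean_metric("RF"))


class TestDurationSweep:
    def _cohort(self):
        from eegsift.synthetic import SynthConfig, generate_cohort

        cfg = SynthConfig(n_subjects_pos=2, n_subjects_neg=2,
                          duration_s=24.0, seed=17)
        return generate_cohort(cfg)

    def test_structural_output(self):
        recs = self._cohort()
        sweep = duration_sweep(recs, [0.2, 0.4], _fast_models(), k=2, seed=0,
                               selector="rank")
        assert len(sweep) == 2  # 2 durations x 1 model
        assert set(sweep["minutes"]) == {0.2, 0.4}
        assert sweep["accuracy"].between(0, 1).all()

    def test_full_length_truncation_equals_untruncated_run(self):
        from eegsift.pipeline import extract_cohort

        recs = self._cohort()
        sweep = duration_sweep(recs, [0.4], _fast_models(), k=2, seed=4,
                               selector="rank")
        fm = extract_cohort(recs)
        direct = run_cv(fm, _fast_models(), k=2, seed=4, selector="rank")
        assert sweep["accuracy"].iloc[0] == pytest.approx(
            direct.mean_metric("RF"))

    def test_overlong_request_rejected(self):
        with pytest.raises(DataError):
            duration_sweep(self._cohort(), [5.0], _fast_models(), k=2, seed=0)
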