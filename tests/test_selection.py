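"""Mutual information, RankSearch prefix rule, GA behaviour, baselines."""

import numpy as np
import pytest

from conftest import planted_feature_matrix
from eegsift.baselines import aco_select, lasso_select, pca_reduce
from eegsift.containers import FeatureMatrix
from eegsift.errors import ConfigError, DataError
from eegsift.selection import (GAConfig, ga_select, make_fitness,
                               mutual_information, rank_search,
                               retained_prefix_count)


def tiny_fm(n_features=6, n_subjects=8, epochs_per_subject=10, seed=0,
            n_informative=2, effect=2.0):
    return planted_feature_matrix(
        n_subjects_per_class=n_subjects // 2,
        epochs_per_subject=epochs_per_subject,
        n_informative=n_informative, n_noise=n_features - n_informative,
        effect_size=effect, seed=seed)


def smoke_ga(seed=0, **kw):
    defaults = dict(population_size=10, generations=5, fitness_cv_folds=3,
                    rf_trees=15, seed=seed)
    defaults.update(kw)
    return GAConfig(**defaults)


class TestMutualInformation:
    def test_feature_identical_to_labels_gives_label_entropy(self):
        labels = np.resize([0, 1], 200)
        mi = mutual_information(labels.astype(float), labels)
        assert mi == pytest.approx(np.log(2), abs=0.05)

    def test_independent_feature_near_zero(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(500)
            y = rng.integers(0, 2, 500)
            assert mutual_information(x, y, seed=seed) <= 0.05

    def test_uniform_discrete_joint_is_zero(self):
        """2x2 joint with p(x,y)=0.25 everywhere: exact independence, the
        plug-in evaluation of the MI sum returns 0."""
        x = np.array([0.0, 0.0, 1.0, 1.0] * 25)
        y = np.array([0, 1, 0, 1] * 25)
        assert mutual_information(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_constant_feature_zero(self):
        assert mutual_information(np.ones(50), np.resize([0, 1], 50)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            mutual_information(np.ones(20), np.ones(10))


class TestRankSearchPrefixRule:
    def test_toy_scores_prefix(self):
        assert retained_prefix_count(np.array([0.5, 0.3, 0.15, 0.05]), 0.95) == 3

    def test_tau_one_retains_all(self):
        assert retained_prefix_count(np.array([0.5, 0.3, 0.15, 0.05]), 1.0) == 4

    def test_equal_scores_need_full_prefix(self):
        assert retained_prefix_count(np.full(10, 0.1), 0.95) == 10

    def test_rank_search_orders_descending_with_index_tiebreak(self):
        fm = tiny_fm(seed=1)
        res = rank_search(fm, tau=0.95, seed=1)
        ranked = res.scores[res.order]
        assert np.all(np.diff(ranked) <= 1e-12)
        # retained prefix is minimal: dropping its last member misses tau
        k = res.n_retained
        if k < fm.n_features and res.scores.sum() > 0:
            cum = np.cumsum(ranked) / res.scores.sum()
            assert cum[k - 1] >= 0.95 - 1e-9
            assert cum[k - 2] < 0.95

    def test_informative_features_rank_first(self):
        fm = tiny_fm(n_features=10, seed=2, effect=2.5)
        res = rank_search(fm, seed=2)
        top2 = {fm.feature_names[i] for i in res.order[:2]}
        assert top2 == {"planted0", "planted1"}

    def test_single_class_labels_rejected(self):
        fm = tiny_fm(seed=3)
        fm.labels[:] = 0
        with pytest.raises(DataError):
            rank_search(fm)

    def test_bad_tau_rejected(self):
        with pytest.raises(ConfigError):
            rank_search(tiny_fm(), tau=1.5)


class TestFitness:
    def test_pure_accuracy_when_no_parsimony(self):
        """With lambda=0 the fitness of a mask is exactly its mean
        subject-grouped CV accuracy (checked against a manual re-run)."""
        fm = tiny_fm(seed=4)
        cfg = smoke_ga(seed=4, parsimony_weight=0.0)
        fit = make_fitness(fm, cfg)
        full = np.ones(fm.n_features, dtype=bool)
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.metrics import accuracy_score

        from eegsift.cv import fold_epoch_indices, subject_folds

        folds = subject_folds(fm.subject_ids, fm.labels, 3, seed=4)
        accs = []
        for f in folds:
            tr, te = fold_epoch_indices(fm.subject_ids, f)
            clf = RandomForestClassifier(n_estimators=15, random_state=4,
                                         n_jobs=1)
            clf.fit(fm.values[tr], fm.labels[tr])
            accs.append(accuracy_score(fm.labels[te],
                                       clf.predict(fm.values[te])))
        assert fit(full) == pytest.approx(np.mean(accs))

    def test_parsimony_penalty_is_exact(self):
        fm = tiny_fm(seed=5)
        mask = np.zeros(fm.n_features, dtype=bool)
        mask[:3] = True
        f0 = make_fitness(fm, smoke_ga(seed=5, parsimony_weight=0.0))(mask)
        f1 = make_fitness(fm, smoke_ga(seed=5, parsimony_weight=0.05))(mask)
        assert f0 - f1 == pytest.approx(0.05 * 3 / fm.n_features)

    def test_empty_mask_is_worst(self):
        fm = tiny_fm(seed=6)
        fit = make_fitness(fm, smoke_ga(seed=6))
        assert fit(np.zeros(fm.n_features, dtype=bool)) == -np.inf


class TestGA:
    def test_fixed_seed_reproducible(self):
        fm = tiny_fm(seed=7)
        scores = rank_search(fm, seed=7).scores
        r1 = ga_select(fm, scores, smoke_ga(seed=7))
        r2 = ga_select(fm, scores, smoke_ga(seed=7))
        np.testing.assert_array_equal(r1.selected_indices, r2.selected_indices)
        assert r1.best_fitness_history == r2.best_fitness_history

    def test_best_fitness_history_nondecreasing_with_elitism(self):
        fm = tiny_fm(n_features=8, seed=8)
        res = ga_select(fm, rank_search(fm, seed=8).scores, smoke_ga(seed=8))
        hist = np.array(res.best_fitness_history)
        assert len(hist) == 5 + 1
        assert np.all(np.diff(hist) >= -1e-12)

    def test_never_returns_empty_subset(self):
        fm = tiny_fm(n_features=6, seed=9, effect=0.0)  # pure noise
        res = ga_select(fm, rank_search(fm, seed=9).scores,
                        smoke_ga(seed=9, mutation_prob=0.5))
        assert len(res.selected_indices) >= 1

    def test_parsimony_shrinks_redundant_subsets(self):
        """With parsimony pressure and mostly-redundant features the elite
        subset ends strictly smaller than it started (majority of 5 seeds)."""
        shrunk = 0
        for seed in range(5):
            fm = planted_feature_matrix(n_subjects_per_class=4,
                                        epochs_per_subject=10,
                                        n_informative=2, n_noise=10,
                                        effect_size=3.0, seed=20 + seed)
            res = ga_select(fm, rank_search(fm, seed=seed).scores,
                            smoke_ga(seed=seed, generations=8,
                                     parsimony_weight=0.2))
            if res.best_size_history[-1] < res.best_size_history[0]:
                shrunk += 1
        assert shrunk >= 3

    def test_histories_have_generations_plus_one_entries(self):
        fm = tiny_fm(seed=10)
        cfg = smoke_ga(seed=10, generations=4)
        res = ga_select(fm, rank_search(fm, seed=10).scores, cfg)
        for h in (res.best_fitness_history, res.best_size_history,
                  res.mean_size_history):
            assert len(h) == 5


class TestBaselines:
    def test_lasso_vanishing_penalty_keeps_all(self):
        fm = tiny_fm(seed=11)
        res = lasso_select(fm, C=1e6, seed=11)
        assert len(res.selected_indices) == fm.n_features

    def test_lasso_target_size_respected_roughly(self):
        fm = tiny_fm(n_features=12, seed=12)
        res = lasso_select(fm, target_size=4, seed=12)
        assert 1 <= len(res.selected_indices) <= 8

    def test_pca_full_rank_is_lossless(self):
        fm = tiny_fm(seed=13)
        res = pca_reduce(fm, k=fm.n_features, seed=13)
        z = res.transformer.transform(fm.values)
        back = res.transformer.named_steps["scale"].inverse_transform(
            res.transformer.named_steps["pca"].inverse_transform(z))
        np.testing.assert_allclose(back, fm.values, atol=1e-8)

    def test_aco_returns_requested_size(self):
        fm = tiny_fm(n_features=10, seed=14)
        res = aco_select(fm, target_size=3, fitness_config=smoke_ga(seed=14),
                         n_ants=5, n_iters=3, seed=14)
        assert len(res.selected_indices) == 3
        assert res.method == "ACO"

    def test_rsga_beats_baselines_on_planted_features(self):
        """Directional comparison on planted-informative data: the
        two-stage selector's wrapper fitness should match or exceed each
        baseline's on the same folds, in a majority of seeds."""
        wins = {"ACO": 0, "LASSO": 0, "PCA": 0}
        n_seeds = 3
        for seed in range(n_seeds):
            fm = planted_feature_matrix(n_subjects_per_class=6,
                                        epochs_per_subject=10,
                                        n_informative=4, n_noise=40,
                                        effect_size=1.0, seed=40 + seed)
            cfg = smoke_ga(seed=seed, population_size=12, generations=6,
                           parsimony_weight=0.01)
            fit = make_fitness(fm, cfg)
            ga = ga_select(fm, rank_search(fm, seed=seed).scores, cfg)
            k = max(1, len(ga.selected_indices))
            ga_acc = fit(np.isin(np.arange(fm.n_features), ga.selected_indices))

            def mask_of(indices):
                return np.isin(np.arange(fm.n_features), indices)

            aco = aco_select(fm, k, cfg, n_ants=6, n_iters=5, seed=seed)
            if ga_acc >= fit(mask_of(aco.selected_indices)) - 1e-9:
                wins["ACO"] += 1
            lasso = lasso_select(fm, target_size=k, seed=seed)
            if len(lasso.selected_indices) == 0 or \
                    ga_acc >= fit(mask_of(lasso.selected_indices)) - 1e-9:
                wins["LASSO"] += 1
            pca = pca_reduce(fm, k, seed=seed)
            # PCA fitness on its transformed space with the same folds
            from eegsift.containers import FeatureMatrix as FM
            pc_fm = FM(values=pca.transformer.transform(fm.values),
                       feature_names=pca.selected_names,
                       subject_ids=fm.subject_ids, labels=fm.labels)
            pc_fit = make_fitness(pc_fm, cfg)
            if ga_acc >= pc_fit(np.ones(k, dtype=bool)) - 1e-9:
                wins["PCA"] += 1
        for method, w in wins.items():
            assert w >= 2, f"RS+GA lost to {method} in {n_seeds - w} seeds"

    def test_pca_bad_k_rejected(self):
        with pytest.raises(DataError):
            pca_reduce(tiny_fm(), k=0)
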