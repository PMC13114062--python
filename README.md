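# eegsift

Multi-domain EEG feature extraction and hybrid two-stage feature
selection for resting-state depression screening.

`eegsift` is a library + CLI for the classic "interpretable ML on short
EEG epochs" workflow used in clinical biomarker research: take a small
cohort of resting-state recordings labelled patient / control, cut them
into overlapping 4-second epochs, compute a broad battery of
time-domain, spectral and nonlinear features per channel, select a
compact discriminative subset, and evaluate standard classifiers under
subject-level cross-validation so that no individual's epochs leak
across the train/test split.

Its core contribution is the **two-stage selector**:

1. **RankSearch** — rank all features by mutual information with the
   label, I(X;Y) = Σ p(x,y) log [p(x,y)/(p(x)p(y))], and keep the
   shortest descending prefix covering τ = 95 % of the total MI score.
2. **Ranking-guided genetic algorithm** — a wrapper GA over binary
   masks of the retained candidates, initialized with gene-inclusion
   probabilities affine in the normalized MI scores. Fitness is the
   subject-grouped 5-fold CV accuracy of a fixed random forest minus a
   small parsimony penalty λ·(|subset|/d); tournament selection,
   uniform crossover (p_c = 0.8), bit-flip mutation (p_m = 0.05), and a
   one-elite hall of fame.

ACO, LASSO and PCA selectors are included as size-matched baselines,
and a seeded synthetic EEG generator (three prefrontal channels,
class-dependent beta power and temporal complexity) makes every stage
testable without any data download.

## Worked example

```python
from eegsift import (SynthConfig, generate_cohort, extract_cohort,
                     run_cv, GAConfig, ModelSpec)

cfg = SynthConfig(n_subjects_pos=10, n_subjects_neg=10,
                  duration_s=60.0, seed=7)
features = extract_cohort(generate_cohort(cfg))
print(features.values.shape)

report = run_cv(
    features,
    models=[ModelSpec("RF", grid={"n_estimators": [100], "max_depth": [None]}),
            ModelSpec("SVM", grid={"C": [1.0, 10.0]})],
    k=10, seed=7, selector="rs+ga",
    ga_config=GAConfig(population_size=12, generations=6,
                       fitness_cv_folds=3, rf_trees=25, seed=7))
best, acc = report.best_model()
print(best, round(acc, 3), round(report.jaccard_mean, 3))
```

prints

```
(580, 93)
SVM 0.84 0.236
```

Twenty 60-second subjects yield 29 epochs each (580 rows) and 93
feature columns (31 measures × 3 channels). Under subject-level
10-fold CV with per-fold re-selection, the best model recovers the
planted class effects well above chance (epoch-level accuracy 0.84 on
this one-minute smoke cohort; accuracy rises with recording length —
the default geometry is 5-minute recordings with 149 epochs per
subject). The mean pairwise Jaccard similarity of the ten per-fold
selected subsets (0.236 here) quantifies how stable the selection is —
it rises toward 1 with stronger effects, longer recordings and larger
GA budgets.

The same pipeline is scriptable from the shell:

```bash
eegsift simulate -c config.yaml     # synthetic cohort -> NPZ + manifest
eegsift run      -c config.yaml     # per-fold selection + 5 classifiers
eegsift duration -c config.yaml -m 1 -m 5
eegsift plot     <run-dir>
```

See `eegsift --help` for the full surface (exit codes: 0 ok, 2 config
error, 3 data error). `docs/methods.md` documents every model,
parameter and numerical convention.

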