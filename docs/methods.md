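# Methods

`eegsift` implements an epoch-level machine-learning pipeline for
two-class resting-state EEG discrimination (patient vs control), built
around a two-stage feature-selection strategy: a mutual-information
filter ("RankSearch") followed by a ranking-guided wrapper genetic
algorithm. This note documents the models, the numerical choices, and
what the synthetic study conditions do and do not establish.

## Signal model and preprocessing

Recordings are continuous multichannel EEG (default analysis channels
Fp1, Fz, Fp2). Preprocessing is:

1. **Bandpass 0.1–45 Hz** — 4th-order Butterworth applied
   forward-backward (`sosfiltfilt`), i.e. zero phase and an effective
   8th-order magnitude response. The 0.1 Hz edge has a multi-second
   impulse response, so the filter is applied to the continuous
   recording, never to individual 4 s epochs.
2. **Wavelet threshold denoising** — per channel, 5-level `db4`
   decomposition, soft thresholding of all detail coefficients at the
   universal threshold σ̂·√(2 ln N), with σ̂ = median(|d₁|)/0.6745
   estimated from the finest detail level. An all-zero (noiseless)
   channel is passed through unchanged.
3. **Segmentation** — sliding window of 4 s with 2 s step; windows
   start at 0, 2 s, 4 s, … and a partial trailing window is dropped
   (floor rule), so a 300 s recording yields exactly
   ⌊(300−4)/2⌋+1 = 149 epochs. Epochs are cut strictly within one
   recording and inherit its subject id and label.

Artifact rejection (ICA, data-driven bad-segment removal) is **out of
scope**: those steps are operator-dependent, and the pipeline assumes
real recordings arrive already artifact-cleaned (`assume_clean` flag).

## Feature battery (31 per channel)

Per 4 s epoch and channel, in fixed column order:

- **Time domain (6):** standard deviation, peak-to-peak amplitude, RMS,
  and the Hjorth parameters — activity var(x), mobility
  √(var(x′)/var(x)), complexity mobility(x′)/mobility(x), with x′ the
  first difference. Constant-signal sentinels: mobility 0,
  complexity 1.
- **Frequency domain (12):** Welch PSD (1 s Hann segments, 50 %
  overlap, density scaling); band powers as trapezoid integrals over
  delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–45 Hz; mean
  PSD and total power over 0.5–45 Hz; peak frequency (lowest frequency
  among ties); spectral asymmetry index SASI = (β−θ)/(β+θ); ratios
  α/β, θ/α, θ/β with machine-epsilon denominator floors.
- **Entropy / complexity (13):** differential entropy (Gaussian closed
  form ½ ln 2πe·var, variance floored at machine ε); sample entropy
  (m=2, r=0.2·σ, Chebyshev ≤ r, self-matches excluded); fuzzy entropy
  (same template scheme, membership exp(−d²/r)); permutation entropy
  (order 3, delay 1, normalized by ln 6, ties broken by temporal
  order); spectral entropy (Shannon entropy of the normalized PSD over
  0.5–45 Hz, divided by ln #bins); wavelet entropy (Shannon entropy of
  the relative energies of the 5 db4 detail levels + approximation);
  SVD entropy (embedding 10, delay 1, normalized singular values,
  /ln 10); Lempel–Ziv complexity (binarize at the median with ties → 0,
  LZ76 greedy parsing where a fully-reproducible tail opens no new
  phrase — hence exactly 1 phrase for a constant sequence — normalized
  by n/log₂n); Higuchi fractal dimension (k_max=10); C0 complexity
  (share of spectral energy in components below the mean spectral
  power); Grassberger–Procaccia correlation dimension (embedding 5,
  delay 2, slope over a log-radius grid spanning the 10th–50th distance
  percentiles); largest Lyapunov exponent (Rosenstein, embedding 5,
  delay 2, divergence slope over the first 0.5 s, Theiler window 20);
  and a Lyapunov-spectrum scalar, the sum of Rosenstein estimates at
  embedding dimensions 1–5 — a pragmatic summary, since a true exponent
  spectrum is not estimable from one 4 s epoch.

The O(n²) estimators (correlation dimension, Lyapunov) run on an
evenly strided subsample of the embedded trajectory (≤ 400 points /
≤ 200 reference points) to bound per-epoch cost; both knobs are in
`FeatureConfig`. Three channels give 93 columns named
`<Measure>_<Channel>`.

Degenerate inputs never produce NaN: each feature documents a finite
limiting convention (e.g. sample entropy 0 on constant signals; peak
frequency reported at the lower band edge for an all-zero epoch).

## Two-stage selection

**Stage 1 — RankSearch.** Each feature's mutual information with the
label is estimated with the kNN estimator (k = 3, nats, clipped at 0;
features with ≤ 10 distinct values use the exact plug-in sum instead).
Features are sorted descending (ties broken by original column index)
and the shortest prefix whose cumulative share of total MI reaches
τ = 0.95 is retained. If all scores are zero, everything is retained.

**Stage 2 — ranking-guided GA.** Binary masks over the retained
candidates. Initialization is biased by the ranking: gene j is switched
on with probability p_min + (p_max−p_min)·MĨ_j, MĨ the min-max
normalized MI score, defaults [0.2, 0.8]. Fitness is the mean
subject-grouped k-fold CV accuracy (default 5 folds) of a fixed random
forest on the masked columns, minus a parsimony term λ·(subset size /
candidate count), λ = 0.01 by default and configurable to 0. Tournament
selection (size 3), uniform crossover with probability 0.8, per-gene
bit-flip mutation 0.05, a one-individual hall of fame (which makes the
best-fitness history non-decreasing), and empty-chromosome repair by
forcing the top-MI gene. Defaults: population 50, 20 generations.
Fitness evaluations are memoized on the mask bits; the same fold
partition and forest seed are reused for every mask so fitnesses are
comparable.

Two deliberately open points, resolved as follows: the parsimony term
is an explicit, small penalty because pure-accuracy fitness exerts no
pressure toward the compact subsets the method is meant to produce;
and an optional linear mutation-rate schedule (2·p_m → p_m/2 across
generations, `adaptive_mutation`, off by default) stands in for
"dynamically adjusted" genetic operators. Ranking guidance beyond
initialization (e.g. rank-biased mutation) is not implemented. The GA
searches the retained candidates by default; passing the full feature
set is possible by skipping stage 1.

**Baselines.** ACO (20 ants, 20 iterations, evaporation 0.2,
fixed-size subsets sampled ∝ pheromone, same wrapper fitness — the
parameters are this package's own defaults), LASSO (L1 logistic path,
penalty chosen from a log grid to match a target nonzero count), and
PCA (top-k components on standardized inputs; a transform, not a
named-feature subset). Baseline subset sizes are matched to the RS+GA
result for comparability.

## Classification and evaluation

Five learners — decision tree, KNN, random forest, RBF SVM, XGBoost —
each tuned by grid search over small default grids (depths {3,5,10,∞};
k {3,5,7,9}; trees {100,300} × depth {∞,10}; C {0.1,1,10}; trees
{100,300} × depth {3,5} × η {0.05,0.1}) using subject-grouped inner CV
(default 3 folds) with accuracy as the criterion, then refit on all
training rows. KNN and SVM are z-scored with statistics learned from
training rows only; tree models consume raw features.

Outer evaluation is stratified subject-level k-fold CV (default k=10):
subjects are shuffled within class and dealt round-robin, so every
fold's class ratio approximates the cohort's and no subject ever
appears on both sides of a split — the essential leakage guard when
overlapping windows from one recording serve as samples. Selection is
re-run from scratch on each fold's training subjects. Metrics are
epoch-level: accuracy, sensitivity TP/(TP+FN), specificity TN/(TN+FP),
F1 = 2TP/(2TP+FP+FN), Cohen's κ = (p_o−p_e)/(1−p_e) with
p_e = Σ_c actual_c·predicted_c / n², and AUC by trapezoidal
integration of the empirical ROC (threshold sweep over unique scores,
ties sharing a point; equals the Mann–Whitney pair-count statistic).
Folds with a single-class test set are flagged and their undefined
metrics excluded from aggregates, which are unweighted means over
folds. Selection stability is the mean off-diagonal pairwise Jaccard
similarity of the per-fold selected subsets (two empty sets count as
identical, one empty vs non-empty as disjoint). Group-difference
reporting uses Welch's t (positive when the control mean exceeds the
patient mean) plus per-feature MI.

## Synthetic study conditions

The generator emulates a 34-patient / 30-control eyes-closed prefrontal
cohort: 3 channels, 256 Hz, 5-minute recordings. Each channel is 1/f
pink noise (unit exponent) + four band oscillations
(delta/theta/alpha/beta) with random carrier frequency and phase and a
slowly drifting Ornstein–Uhlenbeck amplitude envelope (relaxation 2 s,
σ 0.35 — avoids exactly periodic epochs) + white noise, then AR(1)
smoothing with amplitude re-normalization. Class differences, chosen
once to mirror the discriminative markers this kind of data is known
for, at magnitudes the default pipeline can comfortably learn: patients
get a beta-band RMS amplitude of 7.2 vs 4.0 (≈1.8×,
elevated prefrontal beta power), slightly lower alpha (9 vs 10), and a
stronger AR coefficient (0.35 vs 0.05 — smoother waveforms, hence
lower permutation entropy and Hjorth complexity). A null configuration
(identical parameters, AR 0.15 both classes) exists for calibration.
Every recording is a pure function of (seed, subject id, label); the
per-subject stream is keyed on the global seed, a CRC32 hash of the
subject id, and the label.

The generator does **not** simulate ocular/muscle artifacts, volume
conduction or a multi-channel head model, age/gender covariates, or
non-stationarity beyond the OU envelopes. Passing tests on it
therefore establish that the pipeline's machinery is correct and
leakage-free and that planted class structure of realistic effect size
is recovered — not that any particular accuracy will be reached on
real clinical recordings.

## Problem sizes used in tests and the acceptance run

Pipeline-level checks run at reduced scale, chosen as the smallest
cohorts at which the planted effects are comfortably learnable and
chance calibration is stable: 10+10 subjects with 60 s recordings for
the planted/null cross-validated runs (10-fold, GA smoke settings:
population 12, 6 generations, 25-tree forest fitness, 3 fitness
folds); 5+5 subjects, one channel, 300 s recordings for the 1-vs-5
minute duration comparison (RankSearch selector); GA recovery and
exhaustive-search checks on synthetic planted feature tables (73 and 8
candidates). Structural counts (149 epochs/subject, 9536 total, 31/93
features) are computed at the full default geometry.

## Known limitations

- Epoch-level metrics overweight subjects slightly when fold sizes
  differ; subject-level majority voting is not the primary report.
- The kNN MI estimator is itself seeded; rankings on near-tied features
  can differ across seeds (ties in the *scores*, not the estimator, are
  broken deterministically by column index).
- The Lyapunov-spectrum scalar and C0 complexity follow pragmatic,
  configurable definitions; alternative conventions exist.
- LASSO's matched-size path may not reach an exact target count; the
  closest count on the grid is used.
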