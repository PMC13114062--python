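"""Shared fixtures: small synthetic cohorts and feature matrices.

Everything is generated programmatically at test time; session scope
keeps the expensive feature extractions to one run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from eegsift.containers import FeatureMatrix
from eegsift.pipeline import extract_cohort
from eegsift.synthetic import ClassEffect, SynthConfig, generate_cohort, null_effects


@pytest.fixture(scope="session")
def small_cohort():
    """4+4 subjects, 30 s recordings, default planted class effects."""
    cfg = SynthConfig(n_subjects_pos=4, n_subjects_neg=4, duration_s=30.0, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """Feature matrix of the small planted cohort (112 epochs x 93)."""
    return extract_cohort(small_cohort)


def planted_feature_matrix(n_subjects_per_class=10, epochs_per_subject=20,
                           n_informative=5, n_noise=68, effect_size=1.5,
                           seed=0) -> FeatureMatrix:
    """Synthetic feature table with planted informative columns.

    Informative columns carry a class mean shift of ``effect_size``
    pooled SDs plus a per-subject random intercept (epochs within a
    subject are correlated, as in real EEG); noise columns are pure
    N(0,1).  Informative columns come first.
    """
    rng = np.random.default_rng(seed)
    rows, labels, sids = [], [], []
    d = n_informative + n_noise
    for cls in (0, 1):
        for s in range(n_subjects_per_class):
            sid = f"c{cls}s{s:02d}"
            intercept = rng.normal(0, 0.4, size=d)
            for _ in range(epochs_per_subject):
                x = rng.standard_normal(d) + intercept
                if cls == 1:
                    x[:n_informative] += effect_size
                rows.append(x)
                labels.append(cls)
                sids.append(sid)
    names = [f"planted{i}" for i in range(n_informative)] + [
        f"noise{i}" for i in range(n_noise)]
    return FeatureMatrix(values=np.array(rows), feature_names=names,
                         subject_ids=np.array(sids), labels=np.array(labels))


@pytest.fixture()
def planted_fm():
    return planted_feature_matrix(seed=3)


@pytest.fixture(scope="session")
def null_cohort_30s():
    """3+3 subjects with identical class parameters (no planted effect)."""
    cfg = SynthConfig(n_subjects_pos=3, n_subjects_neg=3, duration_s=30.0,
                      seed=5, effect=null_effects())
    return generate_cohort(cfg)


__all__ = ["planted_feature_matrix", "ClassEffect"]
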