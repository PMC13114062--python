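"""Subject-level fold construction.

Folds are built over *subjects*, never epochs, so no individual ever
contributes epochs to both the training and the test side of a split —
the leakage guard required when overlapping windows from the same
recording are used as samples.
"""

from __future__ import annotations

import numpy as np

from .errors import DataError

__all__ = ["subject_folds", "fold_epoch_indices"]


def subject_folds(subject_ids: np.ndarray, labels: np.ndarray, k: int,
                  seed: int) -> list[np.ndarray]:
    """Partition subjects into ``k`` class-stratified folds.

    ``subject_ids``/``labels`` are per-epoch (or per-subject) arrays; the
    subject -> label map is derived from them.  Within each class the
    subjects are shuffled with ``seed`` and dealt round-robin so every
    fold's class ratio approximates the cohort's.  Returns a list of k
    arrays of subject ids (the test subjects of each fold).
    """
    subject_ids = np.asarray(subject_ids)
    labels = np.asarray(labels)
    uniq, first = np.unique(subject_ids, return_index=True)
    sub_labels = labels[first]
    if len(uniq) < k:
        raise DataError(f"cannot make {k} folds from {len(uniq)} subjects")
    rng = np.random.default_rng(seed)
    folds: list[list] = [[] for _ in range(k)]
    offset = 0
    for cls in (1, 0):
        members = uniq[sub_labels == cls]
        members = members[rng.permutation(len(members))]
        for i, sid in enumerate(members):
            folds[(i + offset) % k].append(sid)
        offset += len(members)  # stagger classes so fold sizes balance
    return [np.array(f) for f in folds]


def fold_epoch_indices(subject_ids: np.ndarray,
                       test_subjects: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(train_idx, test_idx) epoch index arrays for one fold."""
    test_mask = np.isin(subject_ids, test_subjects)
    return np.where(~test_mask)[0], np.where(test_mask)[0]
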