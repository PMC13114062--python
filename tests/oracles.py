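"""Naive reference implementations used as independent oracles.

Deliberately written as plain loops / direct textbook formulas so they
share no code path with the package's vectorized implementations.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def sampen_naive(x, m=2, r_factor=0.2):
    """Sample entropy by explicit template loops (Chebyshev, <= r,
    self-matches excluded)."""
    x = np.asarray(x, dtype=float)
    r = r_factor * x.std()
    n = len(x)
    n_templ = n - m  # common template count for lengths m and m+1

    def count(dim):
        total = 0
        for i in range(n_templ):
            for j in range(i + 1, n_templ):
                d = max(abs(x[i + k] - x[j + k]) for k in range(dim))
                if d <= r:
                    total += 1
        return total

    b = count(m)
    if b == 0:
        return 0.0
    a = count(m + 1)
    if a == 0:
        return math.log(b)
    return -math.log(a / b)


def perm_entropy_naive(x, order=3, delay=1):
    """Normalized permutation entropy via a Counter of ordinal tuples."""
    x = np.asarray(x, dtype=float)
    patterns = Counter()
    for i in range(len(x) - (order - 1) * delay):
        window = [x[i + k * delay] for k in range(order)]
        patterns[tuple(np.argsort(window, kind="stable"))] += 1
    total = sum(patterns.values())
    h = -sum((c / total) * math.log(c / total) for c in patterns.values())
    return h / math.log(math.factorial(order))


def spectral_entropy_naive(freqs, psd, lo=0.5, hi=45.0):
    """Normalized Shannon entropy of a PSD restricted to [lo, hi]."""
    p = [v for f, v in zip(freqs, psd) if lo <= f <= hi]
    total = sum(p)
    if total <= 0:
        return 0.0
    h = -sum((v / total) * math.log(v / total) for v in p if v > 0)
    return h / math.log(len(p))


def svd_entropy_naive(x, dim=10, delay=1):
    """SVD entropy by building the trajectory matrix row by row."""
    x = np.asarray(x, dtype=float)
    rows = []
    i = 0
    while i + (dim - 1) * delay < len(x):
        rows.append([x[i + k * delay] for k in range(dim)])
        i += 1
    s = np.linalg.svd(np.array(rows), compute_uv=False)
    p = s / s.sum()
    h = -sum(v * math.log(v) for v in p if v > 0)
    return h / math.log(dim)


def higuchi_naive(x, k_max=10):
    """Higuchi FD by the direct textbook double loop."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    log_l, log_invk = [], []
    for k in range(1, k_max + 1):
        lm = []
        for m in range(k):
            n_m = (n - 1 - m) // k
            if n_m < 1:
                continue
            length = sum(abs(x[m + i * k] - x[m + (i - 1) * k])
                         for i in range(1, n_m + 1))
            lm.append(length * (n - 1) / (n_m * k) / k)
        if lm and np.mean(lm) > 0:
            log_l.append(math.log(float(np.mean(lm))))
            log_invk.append(math.log(1.0 / k))
    return float(np.polyfit(log_invk, log_l, 1)[0])


def auc_pair_count(y_true, scores):
    """AUC as the Mann-Whitney pair-count statistic: fraction of
    (positive, negative) pairs ranked concordantly, ties counted 1/2."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    wins = half = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                half += 1
    return (wins + 0.5 * half) / (len(pos) * len(neg))


def lz76_reference_cases():
    """Hand-traced LZ76 parsings: (binary string, phrase count).

    Greedy parsing where a phrase ends at the first symbol that makes it
    novel relative to everything before it, and a fully-reproducible
    tail does not open a new phrase.
    """
    return [
        ("0000000", 1),    # "0" | tail reproducible
        ("01", 2),         # "0" | "1"
        ("010101010", 2),  # "0" | "1" | alternating tail reproducible
        ("0100", 3),       # "0" | "1" | "00" (novel second zero-pair)
    ]
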