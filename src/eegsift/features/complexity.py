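"""Entropy and nonlinear-dynamics features.

Thirteen scalars per epoch: differential, sample, permutation, spectral,
wavelet, fuzzy and SVD entropies, Lempel-Ziv complexity, Higuchi fractal
dimension, C0 complexity, correlation dimension, the largest Lyapunov
exponent, and a scalar summary of the Lyapunov exponent spectrum.

Conventions for degenerate (constant / zero-variance) inputs are chosen
so every feature is finite and deterministic; they are documented on
each function.  The O(n^2) estimators (correlation dimension, Lyapunov)
operate on an evenly strided subsample of the embedded trajectory to
keep per-epoch cost bounded; the subsample sizes are configurable.
"""

from __future__ import annotations

import math
import warnings
from contextlib import contextmanager

import numpy as np
import pywt
from scipy.spatial.distance import cdist, pdist

from .spectral import power_spectrum

ENTROPY_FEATURE_NAMES = [
    "DifferentialEntropy",
    "SampleEntropy",
    "PermutationEntropy",
    "SpectralEntropy",
    "WaveletEntropy",
    "FuzzyEntropy",
    "SVDEntropy",
    "LempelZivComplexity",
    "HiguchiFD",
    "C0Complexity",
    "CorrelationDimension",
    "LargestLyapunov",
    "LyapunovSpectrumSum",
]

_EPS = np.finfo(float).eps


@contextmanager
def warnings_suppressed():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        yield


def differential_entropy(x: np.ndarray) -> float:
    """Gaussian closed form 0.5*ln(2*pi*e*var(x)) on the broadband signal.

    Variance is floored at machine epsilon so a constant signal returns a
    large-negative but finite value instead of -inf.
    """
    var = max(float(np.var(x)), _EPS)
    return 0.5 * math.log(2.0 * math.pi * math.e * var)


def _embed(x: np.ndarray, dim: int, delay: int) -> np.ndarray:
    n = x.size - (dim - 1) * delay
    if n < 1:
        raise ValueError("signal too short for requested embedding")
    idx = np.arange(n)[:, None] + np.arange(dim)[None, :] * delay
    return x[idx]


def sample_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Sample entropy: -ln(A/B) with A, B the counts of template pairs
    (Chebyshev distance <= r, self-matches excluded) of length m+1 and m.

    r = r_factor * std(x).  Constant signal -> 0 (all templates match,
    -ln 1).  If no m-length pair matches, 0 is returned (no evidence);
    if m-pairs match but no (m+1)-pair does, the finite upper bound
    ln(B) is returned instead of infinity.
    """
    x = np.asarray(x, dtype=float)
    r = r_factor * float(np.std(x))
    if r == 0.0:
        return 0.0

    def _pair_count(dim: int) -> int:
        templ = _embed(x, dim, 1)[: x.size - m]  # same template count for m, m+1
        d = cdist(templ, templ, metric="chebyshev")
        n = templ.shape[0]
        return int(((d <= r).sum() - n) // 2)

    b = _pair_count(m)
    if b == 0:
        return 0.0
    a = _pair_count(m + 1)
    if a == 0:
        return float(np.log(b))
    return float(-np.log(a / b))


def fuzzy_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Fuzzy entropy: like sample entropy but with graded membership
    exp(-d^2/r) instead of a hard distance threshold.

    Returns -ln(phi_{m+1}/phi_m) with phi the mean pairwise membership.
    Constant signal -> 0.
    """
    x = np.asarray(x, dtype=float)
    r = r_factor * float(np.std(x))
    if r == 0.0:
        return 0.0

    def _phi(dim: int) -> float:
        templ = _embed(x, dim, 1)[: x.size - m]
        d = pdist(templ, metric="chebyshev")
        return float(np.mean(np.exp(-(d**2) / r)))

    phi_m = _phi(m)
    phi_m1 = _phi(m + 1)
    if phi_m <= 0 or phi_m1 <= 0:
        return 0.0
    return float(-np.log(phi_m1 / phi_m))


def permutation_entropy(x: np.ndarray, order: int = 3, delay: int = 1,
                        normalize: bool = True) -> float:
    """Permutation entropy: Shannon entropy of ordinal patterns.

    Ties are broken by temporal order (stable argsort).  Normalized by
    ln(order!) so the value lies in [0, 1]; a monotone ramp gives 0 and
    iid noise approaches 1.
    """
    x = np.asarray(x, dtype=float)
    windows = _embed(x, order, delay)
    ranks = np.argsort(windows, axis=1, kind="stable")
    base = order ** np.arange(order)
    codes = ranks @ base
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    if normalize:
        h /= math.log(math.factorial(order))
    return h


def spectral_entropy(x: np.ndarray, fs: float, lo: float = 0.5, hi: float = 45.0,
                     seg_s: float = 1.0, overlap: float = 0.5) -> float:
    """Shannon entropy of the Welch PSD normalized to a probability
    vector over [lo, hi], divided by ln(#bins); 0 for a zero signal."""
    freqs, psd = power_spectrum(np.asarray(x, dtype=float), fs,
                                seg_s=seg_s, overlap=overlap)
    mask = (freqs >= lo) & (freqs <= hi)
    p = psd[mask]
    total = p.sum()
    if total <= 0 or p.size < 2:
        return 0.0
    p = p / total
    nz = p > 0
    h = float(-(p[nz] * np.log(p[nz])).sum())
    return h / math.log(p.size)


def wavelet_entropy(x: np.ndarray, wavelet: str = "db4", level: int = 5) -> float:
    """Shannon entropy (nats) of the relative energies of the detail
    levels 1..level plus the final approximation."""
    coeffs = pywt.wavedec(np.asarray(x, dtype=float), wavelet, level=level)
    energies = np.array([float(np.sum(c**2)) for c in coeffs])
    total = energies.sum()
    if total <= 0:
        return 0.0
    p = energies / total
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def svd_entropy(x: np.ndarray, dim: int = 10, delay: int = 1) -> float:
    """Entropy of the normalized singular values of the delay-embedding
    matrix, normalized by ln(dim); 0 for a constant signal."""
    y = _embed(np.asarray(x, dtype=float), dim, delay)
    s = np.linalg.svd(y, compute_uv=False)
    total = s.sum()
    if total <= 0:
        return 0.0
    p = s / total
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum()) / math.log(dim)


def lz76_phrase_count(bits: np.ndarray) -> int:
    """Number of phrases in the LZ76 greedy parsing of a binary sequence.

    Each phrase is the shortest prefix of the remaining sequence that has
    not occurred as a substring of everything seen so far (history plus
    the phrase minus its last symbol).  A trailing remainder that is
    fully reproducible from the history does not open a new phrase, so a
    constant sequence parses into exactly one phrase.
    """
    s = "".join("1" if b else "0" for b in np.asarray(bits).astype(bool))
    n = len(s)
    i, c = 0, 0
    while i < n:
        l = 1
        while i + l <= n and s[i:i + l] in s[: i + l - 1]:
            l += 1
        if i + l > n:  # reproducible tail
            if i == 0:
                c += 1
            break
        c += 1
        i += l
    return c


def lempel_ziv_complexity(x: np.ndarray) -> float:
    """Normalized LZ76 complexity: binarize at the median (x > median -> 1,
    ties -> 0), count phrases, normalize by n/log2(n)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return 0.0
    bits = x > np.median(x)
    c = lz76_phrase_count(bits)
    return float(c * np.log2(n) / n)


def higuchi_fd(x: np.ndarray, k_max: int = 10) -> float:
    """Higuchi fractal dimension (1 for a straight line, ~2 for white
    noise): slope of log L(k) against log(1/k) for k = 1..k_max."""
    x = np.asarray(x, dtype=float)
    n = x.size
    lks = []
    ks = []
    for k in range(1, k_max + 1):
        lengths = []
        for m_off in range(k):
            sub = x[m_off::k]
            if sub.size < 2:
                continue
            nm = sub.size
            # curve length normalized by the Higuchi factor
            norm = (n - 1) / (k * (nm - 1))
            lengths.append(np.sum(np.abs(np.diff(sub))) * norm / k)
        if lengths:
            mean_l = float(np.mean(lengths))
            if mean_l > 0:
                lks.append(math.log(mean_l))
                ks.append(math.log(1.0 / k))
    if len(ks) < 2:
        return 1.0
    slope = np.polyfit(ks, lks, 1)[0]
    return float(slope)


def c0_complexity(x: np.ndarray) -> float:
    """C0 complexity: fraction of spectral energy carried by components
    whose power lies below the mean spectral power (the 'irregular' part
    left after removing the dominant regular components)."""
    x = np.asarray(x, dtype=float)
    spec = np.fft.rfft(x)
    p = np.abs(spec) ** 2
    total = p.sum()
    if total <= 0:
        return 0.0
    removed = p[p < p.mean()].sum()
    return float(removed / total)


def _strided_subsample(n: int, max_points: int) -> np.ndarray:
    if n <= max_points:
        return np.arange(n)
    return np.unique(np.linspace(0, n - 1, max_points).astype(int))


def correlation_dimension(x: np.ndarray, dim: int = 5, delay: int = 2,
                          n_radii: int = 8, max_points: int = 400) -> float:
    """Grassberger-Procaccia correlation dimension.

    Delay embedding, correlation sums C(r) on a log-radius grid spanning
    the 10th-50th percentile of pairwise distances, slope of log C vs
    log r.  The embedded trajectory is evenly strided down to at most
    ``max_points`` points.  Degenerate signals return 0.
    """
    y = _embed(np.asarray(x, dtype=float), dim, delay)
    y = y[_strided_subsample(y.shape[0], max_points)]
    d = pdist(y)
    d = d[d > 0]
    if d.size < 10:
        return 0.0
    r_lo, r_hi = np.percentile(d, [10.0, 50.0])
    if r_lo <= 0 or r_hi <= r_lo:
        return 0.0
    radii = np.exp(np.linspace(np.log(r_lo), np.log(r_hi), n_radii))
    c = np.array([np.mean(d < r) for r in radii])
    keep = c > 0
    if keep.sum() < 2:
        return 0.0
    slope = np.polyfit(np.log(radii[keep]), np.log(c[keep]), 1)[0]
    return float(max(slope, 0.0))


def largest_lyapunov(x: np.ndarray, fs: float, dim: int = 5, delay: int = 2,
                     fit_s: float = 0.5, theiler: int = 20,
                     n_ref: int = 200) -> float:
    """Largest Lyapunov exponent by the Rosenstein method (1/s).

    For up to ``n_ref`` reference points, find the nearest neighbour
    outside a Theiler exclusion window, track the log divergence of the
    pair over the first ``fit_s`` seconds, and fit a line to the mean
    log-divergence curve.  Regular signals give values near (or below)
    zero, chaotic/stochastic ones positive values.
    """
    x = np.asarray(x, dtype=float)
    try:
        y = _embed(x, dim, delay)
    except ValueError:
        return 0.0
    n = y.shape[0]
    k_max = min(int(round(fit_s * fs)), n - 2)
    if k_max < 2 or n < theiler + 3:
        return 0.0
    usable = n - k_max  # pairs must be trackable for k_max steps
    if usable < 2:
        return 0.0
    refs = _strided_subsample(usable, n_ref)
    d = cdist(y[refs], y[:usable])
    ii = refs[:, None]
    jj = np.arange(usable)[None, :]
    d[np.abs(ii - jj) <= theiler] = np.inf
    nbrs = np.argmin(d, axis=1)
    finite = np.isfinite(d[np.arange(len(refs)), nbrs])
    refs, nbrs = refs[finite], nbrs[finite]
    if len(refs) == 0:
        return 0.0
    ks = np.arange(k_max + 1)
    # divergence curves: ||y[i+k] - y[j+k]|| for each pair, vectorized
    i_idx = refs[:, None] + ks[None, :]
    j_idx = nbrs[:, None] + ks[None, :]
    dist = np.linalg.norm(y[i_idx] - y[j_idx], axis=2)
    with np.errstate(divide="ignore"):
        log_div = np.where(dist > 0, np.log(dist), np.nan)
    with warnings_suppressed():
        mean_curve = np.nanmean(log_div, axis=0)
    valid = np.isfinite(mean_curve)
    if valid.sum() < 2:
        return 0.0
    slope = np.polyfit(ks[valid] / fs, mean_curve[valid], 1)[0]
    return float(slope)


def lyapunov_spectrum_sum(x: np.ndarray, fs: float, max_dim: int = 5,
                          delay: int = 2, **kwargs) -> float:
    """Scalar summary of the Lyapunov exponent spectrum: the sum of the
    Rosenstein estimates at embedding dimensions 1..max_dim.

    A pragmatic scalarization — the full spectrum is not estimable from
    a single short epoch with the Rosenstein method, but the sum over
    embedding dimensions tracks overall divergence strength and is
    sensitive to the same regular-vs-irregular contrast.
    """
    return float(sum(
        largest_lyapunov(x, fs, dim=d, delay=delay, **kwargs)
        for d in range(1, max_dim + 1)
    ))
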