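"""Frequency-domain features from a Welch power spectral density.

Band powers integrate the PSD over the canonical EEG rhythm bands;
SASI is the spectral asymmetry index (beta - theta)/(beta + theta).
"""

from __future__ import annotations

import numpy as np
from scipy.signal import welch

FREQ_FEATURE_NAMES = [
    "DeltaPower",
    "ThetaPower",
    "AlphaPower",
    "BetaPower",
    "GammaPower",
    "MeanPower",
    "TotalPower",
    "PeakFrequency",
    "SASI",
    "AlphaBetaRatio",
    "ThetaAlphaRatio",
    "ThetaBetaRatio",
]

#: (low, high) Hz of each analysis band
DEFAULT_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

_EPS = np.finfo(float).eps


def power_spectrum(x: np.ndarray, fs: float, seg_s: float = 1.0,
                   overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD: Hann-tapered segments of ``seg_s`` seconds with
    ``overlap`` fractional overlap; density scaling (power/Hz)."""
    nperseg = min(int(round(seg_s * fs)), x.size)
    noverlap = int(round(overlap * nperseg))
    return welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
                 detrend="constant", scaling="density")


def band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Integral of the PSD over [lo, hi] (trapezoid on the in-band bins)."""
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def freq_features(x: np.ndarray, fs: float, bands: dict | None = None,
                  seg_s: float = 1.0, overlap: float = 0.5,
                  total_lo: float = 0.5, total_hi: float = 45.0) -> dict[str, float]:
    """The twelve frequency-domain features of one 1-D epoch.

    For an all-zero epoch every power is 0, the ratios are 0 (floored
    denominators) and the peak frequency is reported at the lower edge
    of the analysis range.
    """
    bands = bands or DEFAULT_BANDS
    x = np.asarray(x, dtype=float)
    freqs, psd = power_spectrum(x, fs, seg_s=seg_s, overlap=overlap)
    powers = {name: band_power(freqs, psd, lo, hi) for name, (lo, hi) in bands.items()}
    total = band_power(freqs, psd, total_lo, total_hi)
    in_range = (freqs >= total_lo) & (freqs <= total_hi)
    if total <= 0 or not np.any(psd[in_range] > 0):
        mean_power = 0.0
        peak = total_lo
    else:
        mean_power = float(np.mean(psd[in_range]))
        sub = psd[in_range]
        # lowest frequency among tied maxima
        peak = float(freqs[in_range][int(np.argmax(sub))])
    beta, theta, alpha = powers["beta"], powers["theta"], powers["alpha"]
    sasi_den = beta + theta
    sasi = (beta - theta) / sasi_den if sasi_den > _EPS else 0.0
    return {
        "DeltaPower": powers["delta"],
        "ThetaPower": theta,
        "AlphaPower": alpha,
        "BetaPower": beta,
        "GammaPower": powers["gamma"],
        "MeanPower": mean_power,
        "TotalPower": total,
        "PeakFrequency": peak,
        "SASI": float(sasi),
        "AlphaBetaRatio": float(alpha / max(beta, _EPS)) if alpha > 0 else 0.0,
        "ThetaAlphaRatio": float(theta / max(alpha, _EPS)) if theta > 0 else 0.0,
        "ThetaBetaRatio": float(theta / max(beta, _EPS)) if theta > 0 else 0.0,
    }
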