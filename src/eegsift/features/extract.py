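"""Epoch-level feature extraction: 31 features per channel.

Per channel the column order is the 6 time-domain features, the 12
frequency-domain features, then the 13 entropy/complexity features;
channels are the outer loop, so a 3-channel epoch set yields a
93-column matrix with names like ``BetaPower_Fp1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..containers import EpochSet, FeatureMatrix
from ..errors import DataError
from . import complexity as cx
from .spectral import DEFAULT_BANDS, FREQ_FEATURE_NAMES, freq_features
from .timedomain import TIME_FEATURE_NAMES, time_features

FEATURE_NAMES_PER_CHANNEL = (
    TIME_FEATURE_NAMES + FREQ_FEATURE_NAMES + cx.ENTROPY_FEATURE_NAMES
)
N_FEATURES_PER_CHANNEL = len(FEATURE_NAMES_PER_CHANNEL)  # 31


@dataclass
class FeatureConfig:
    """Parameters of the feature battery.

    PSD settings feed every spectral quantity; the entropy parameters
    follow common EEG practice (sample/fuzzy entropy with m=2 and
    r=0.2*std, permutation order 3, SVD embedding 10, Higuchi k_max 10).
    ``heavy_max_points`` / ``lyap_n_ref`` bound the O(n^2) estimators.
    """

    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    psd_seg_s: float = 1.0
    psd_overlap: float = 0.5
    total_lo: float = 0.5
    total_hi: float = 45.0
    entropy_m: int = 2
    entropy_r_factor: float = 0.2
    perm_order: int = 3
    perm_delay: int = 1
    svd_dim: int = 10
    svd_delay: int = 1
    higuchi_k_max: int = 10
    corr_dim: int = 5
    corr_delay: int = 2
    lyap_dim: int = 5
    lyap_delay: int = 2
    lyap_fit_s: float = 0.5
    wavelet: str = "db4"
    wavelet_level: int = 5
    heavy_max_points: int = 400
    lyap_n_ref: int = 200

    def __post_init__(self) -> None:
        if self.entropy_m < 1 or self.perm_order < 2 or self.higuchi_k_max < 2:
            raise DataError("invalid entropy parameters")
        lows = sorted(lo for lo, _ in self.bands.values())
        his = [self.bands[k][1] for k in self.bands]
        if min(lows) <= 0:
            raise DataError("band edges must be positive")
        del his


def entropy_features(x: np.ndarray, fs: float,
                     config: FeatureConfig | None = None) -> dict[str, float]:
    """The thirteen entropy/complexity features of one 1-D epoch."""
    cfg = config or FeatureConfig()
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise DataError("epoch too short for entropy features (need >= 64)")
    if not np.all(np.isfinite(x)):
        raise DataError("non-finite samples in epoch")
    # one Rosenstein run per embedding dimension; the run at lyap_dim
    # doubles as the largest-exponent estimate
    lles = [
        cx.largest_lyapunov(x, fs, dim=d, delay=cfg.lyap_delay,
                            fit_s=cfg.lyap_fit_s, n_ref=cfg.lyap_n_ref)
        for d in range(1, cfg.lyap_dim + 1)
    ]
    return {
        "DifferentialEntropy": cx.differential_entropy(x),
        "SampleEntropy": cx.sample_entropy(x, cfg.entropy_m, cfg.entropy_r_factor),
        "PermutationEntropy": cx.permutation_entropy(x, cfg.perm_order, cfg.perm_delay),
        "SpectralEntropy": cx.spectral_entropy(
            x, fs, cfg.total_lo, cfg.total_hi, cfg.psd_seg_s, cfg.psd_overlap),
        "WaveletEntropy": cx.wavelet_entropy(x, cfg.wavelet, cfg.wavelet_level),
        "FuzzyEntropy": cx.fuzzy_entropy(x, cfg.entropy_m, cfg.entropy_r_factor),
        "SVDEntropy": cx.svd_entropy(x, cfg.svd_dim, cfg.svd_delay),
        "LempelZivComplexity": cx.lempel_ziv_complexity(x),
        "HiguchiFD": cx.higuchi_fd(x, cfg.higuchi_k_max),
        "C0Complexity": cx.c0_complexity(x),
        "CorrelationDimension": cx.correlation_dimension(
            x, cfg.corr_dim, cfg.corr_delay, max_points=cfg.heavy_max_points),
        "LargestLyapunov": lles[-1],
        "LyapunovSpectrumSum": float(sum(lles)),
    }


def channel_features(x: np.ndarray, fs: float,
                     config: FeatureConfig | None = None) -> dict[str, float]:
    """All 31 features of one channel of one epoch, in canonical order."""
    cfg = config or FeatureConfig()
    out = dict(time_features(x))
    out.update(freq_features(x, fs, bands=cfg.bands, seg_s=cfg.psd_seg_s,
                             overlap=cfg.psd_overlap, total_lo=cfg.total_lo,
                             total_hi=cfg.total_hi))
    out.update(entropy_features(x, fs, cfg))
    return {name: out[name] for name in FEATURE_NAMES_PER_CHANNEL}


def feature_names_for(channel_names: list[str]) -> list[str]:
    return [f"{meas}_{ch}" for ch in channel_names
            for meas in FEATURE_NAMES_PER_CHANNEL]


def extract(epochs: EpochSet, config: FeatureConfig | None = None,
            progress: bool = False) -> FeatureMatrix:
    """Compute the full feature matrix of an epoch set.

    Column order: channels outer (in ``epochs.channel_names`` order),
    the 31-measure battery inner.  Subject ids and labels pass through.
    """
    cfg = config or FeatureConfig()
    names = feature_names_for(epochs.channel_names)
    n_ep, n_ch, _ = epochs.epochs.shape
    values = np.empty((n_ep, n_ch * N_FEATURES_PER_CHANNEL))
    iterator = range(n_ep)
    if progress:
        from tqdm import tqdm  # pragma: no cover - cosmetic

        iterator = tqdm(iterator, desc="extract")  # pragma: no cover
    for ei in iterator:
        row = []
        for ci in range(n_ch):
            feats = channel_features(epochs.epochs[ei, ci], epochs.fs, cfg)
            row.extend(feats.values())
        values[ei] = row
    if not np.all(np.isfinite(values)):
        raise DataError("non-finite feature values produced")
    return FeatureMatrix(
        values=values,
        feature_names=names,
        subject_ids=epochs.subject_ids.copy(),
        labels=epochs.labels.copy(),
    )
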