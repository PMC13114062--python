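"""Cohort-level orchestration: recordings -> epochs -> feature matrix."""

from __future__ import annotations

from .containers import EpochSet, FeatureMatrix, Recording
from .features import FeatureConfig, extract
from .preprocess import preprocess_recording

__all__ = ["epochs_from_cohort", "extract_cohort"]


def epochs_from_cohort(recordings: list[Recording], low_hz: float = 0.1,
                       high_hz: float = 45.0, denoise: bool = True,
                       window_s: float = 4.0, step_s: float = 2.0) -> EpochSet:
    """Preprocess and segment each recording, then stack the epochs.

    Epochs are cut strictly within each recording — subjects are never
    concatenated, so no epoch spans a recording boundary.
    """
    parts = [
        preprocess_recording(rec, low_hz=low_hz, high_hz=high_hz,
                             denoise=denoise, window_s=window_s, step_s=step_s)
        for rec in recordings
    ]
    return EpochSet.concatenate(parts)


def extract_cohort(recordings: list[Recording],
                   feature_config: FeatureConfig | None = None,
                   progress: bool = False, **preprocess_kwargs) -> FeatureMatrix:
    """Full front half of the pipeline: preprocess, segment, extract."""
    epochs = epochs_from_cohort(recordings, **preprocess_kwargs)
    return extract(epochs, feature_config, progress=progress)
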