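"""Preprocessing: file readers, bandpass filtering, wavelet denoising,
sliding-window segmentation.

The analysis order is bandpass -> wavelet denoise -> segment.  Artifact
rejection by ICA or data-driven segment removal is intentionally not
implemented: those steps are operator-dependent and real recordings are
expected to arrive already artifact-cleaned (see the ``assume_clean``
flag on :func:`preprocess_recording`).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pywt
from scipy.signal import butter, sosfiltfilt

from .containers import EpochSet, Recording
from .errors import ConfigError, DataError

__all__ = [
    "bandpass",
    "wavelet_denoise",
    "segment",
    "n_epochs_expected",
    "read_recording",
    "preprocess_recording",
]


def bandpass(recording: Recording, low_hz: float = 0.1, high_hz: float = 45.0,
             order: int = 4) -> Recording:
    """Zero-phase Butterworth bandpass; length and metadata preserved.

    A 4th-order Butterworth is applied forward and backward
    (``sosfiltfilt``), doubling the effective order and cancelling phase
    distortion — the standard choice for offline EEG filtering.
    """
    nyq = recording.fs / 2.0
    if not (0 <= low_hz < high_hz < nyq):
        raise ConfigError(
            f"band ({low_hz}, {high_hz}) must satisfy 0 <= low < high < fs/2={nyq}"
        )
    if low_hz == 0:
        sos = butter(order, high_hz, btype="lowpass", fs=recording.fs, output="sos")
    else:
        sos = butter(order, [low_hz, high_hz], btype="bandpass",
                     fs=recording.fs, output="sos")
    filtered = sosfiltfilt(sos, recording.samples, axis=1)
    return recording.with_samples(filtered)


def _universal_soft_threshold(x: np.ndarray, wavelet: str, level: int) -> np.ndarray:
    coeffs = pywt.wavedec(x, wavelet, level=level)
    d1 = coeffs[-1]  # finest detail level carries mostly noise
    sigma = np.median(np.abs(d1)) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(x.size))
    if thr == 0.0:  # noiseless (e.g. all-zero) channel: nothing to shrink
        return x.copy()
    new = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]]
    return pywt.waverec(new, wavelet)[: x.size]


def wavelet_denoise(recording: Recording, wavelet: str = "db4",
                    level: int = 5) -> Recording:
    """Per-channel wavelet-threshold denoising.

    Multilevel DWT, soft thresholding of all detail coefficients at the
    universal threshold sigma*sqrt(2 ln N) with sigma estimated from the
    finest detail level as median(|d1|)/0.6745, then reconstruction to
    the original length.
    """
    n = recording.n_samples
    if n < 2**level:
        raise DataError(
            f"signal of {n} samples too short for a {level}-level decomposition"
        )
    out = np.empty_like(recording.samples)
    for i in range(recording.n_channels):
        out[i] = _universal_soft_threshold(recording.samples[i], wavelet, level)
    return recording.with_samples(out)


def n_epochs_expected(duration_s: float, window_s: float, step_s: float) -> int:
    """floor((duration - window)/step) + 1; partial trailing windows dropped."""
    return int(np.floor((duration_s - window_s) / step_s + 1e-9)) + 1


def segment(recording: Recording, window_s: float = 4.0,
            step_s: float = 2.0) -> EpochSet:
    """Cut a recording into overlapping fixed-length epochs.

    Windows start at 0, step_s, 2*step_s, ...; a window that would run
    past the end of the recording is dropped (no partial epochs).  A
    300 s recording at 4 s / 2 s therefore yields 149 epochs.
    """
    if step_s <= 0:
        raise ConfigError("step_s must be positive")
    win = int(round(window_s * recording.fs))
    step = int(round(step_s * recording.fs))
    n = recording.n_samples
    if win > n:
        raise DataError(
            f"window of {window_s}s exceeds recording of {recording.duration_s:.3g}s"
        )
    starts = np.arange(0, n - win + 1, step)
    epochs = np.stack([recording.samples[:, s:s + win] for s in starts])
    return EpochSet(
        epochs=epochs,
        subject_ids=np.array([recording.subject_id] * len(starts)),
        labels=np.array([recording.label] * len(starts)),
        fs=recording.fs,
        channel_names=list(recording.channel_names),
        window_s=window_s,
        step_s=step_s,
    )


# ---------------------------------------------------------------------------
# readers


def _read_npz(path: Path) -> Recording:
    with np.load(path, allow_pickle=False) as z:
        return Recording(
            subject_id=str(z["subject_id"]),
            label=int(z["label"]),
            channel_names=[str(c) for c in z["channel_names"]],
            fs=float(z["fs"]),
            samples=z["samples"],
        )


def _read_csv(path: Path) -> Recording:
    """CSV of channels x samples with a JSON sidecar ``<stem>.json``
    holding fs, channel_names, subject_id, label."""
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise DataError(f"CSV recording {path} needs a JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    samples = np.loadtxt(path, delimiter=",", ndmin=2)
    return Recording(
        subject_id=str(meta["subject_id"]),
        label=int(meta["label"]),
        channel_names=list(meta["channel_names"]),
        fs=float(meta["fs"]),
        samples=samples,
    )


def _read_edf(path: Path, subject_id: str | None, label: int | None) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise DataError("EDF support requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if label is None:
        raise DataError("EDF files carry no class label; pass label explicitly")
    return Recording(
        subject_id=subject_id or path.stem,
        label=int(label),
        channel_names=list(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        samples=raw.get_data(),
    )


def read_recording(path, fmt: str | None = None, channels: list[str] | None = None,
                   subject_id: str | None = None, label: int | None = None) -> Recording:
    """Read a recording from NPZ, CSV(+JSON sidecar) or EDF.

    ``channels`` optionally restricts (and orders) the channel subset;
    a requested channel absent from the file is an error.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "npz":
        rec = _read_npz(path)
    elif fmt == "csv":
        rec = _read_csv(path)
    elif fmt == "edf":
        rec = _read_edf(path, subject_id, label)
    else:
        raise DataError(f"unknown recording format: {fmt!r}")
    if channels is not None:
        rec = rec.pick_channels(list(channels))
    return rec


def preprocess_recording(recording: Recording, low_hz: float = 0.1,
                         high_hz: float = 45.0, denoise: bool = True,
                         window_s: float = 4.0, step_s: float = 2.0,
                         assume_clean: bool = True) -> EpochSet:
    """Full preprocessing chain for one recording: bandpass -> (denoise)
    -> segment.

    ``assume_clean`` documents that gross artifacts (ocular, muscle) are
    expected to have been removed upstream; no artifact rejection is
    performed here.
    """
    rec = bandpass(recording, low_hz, high_hz)
    if denoise:
        rec = wavelet_denoise(rec)
    return segment(rec, window_s=window_s, step_s=step_s)
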