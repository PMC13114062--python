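"""Seeded two-class synthetic resting-state EEG generator.

Emulates the structure of an eyes-closed prefrontal EEG cohort (three
channels Fp1/Fz/Fp2, 5-minute recordings) with class-dependent signal
properties that mirror the markers known to separate depressed patients
from controls in this kind of data: elevated prefrontal beta-band power
in the patient class, and reduced temporal complexity / permutation
entropy, implemented through a stronger AR(1) smoothing of the patient
signals.

Each channel is built as

    pink 1/f^alpha background
    + per-band oscillations (delta/theta/alpha/beta) with random-phase
      carriers and slowly drifting Ornstein-Uhlenbeck amplitude envelopes
    + white measurement noise,

then passed through a per-class AR(1) filter ``y[t] = a*y[t-1] + x[t]``.
A higher AR coefficient smooths the waveform, lowering permutation
entropy and Hjorth complexity without touching the oscillation
amplitudes directly.

Everything is a pure function of ``(seed, subject_id, label)``: the
per-subject random stream is keyed on the global seed, a CRC32 hash of
the subject id, and the label, so cohorts are bit-reproducible and
subjects are independent.
"""

from __future__ import annotations

import csv
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import Recording
from .errors import ConfigError

__all__ = ["ClassEffect", "SynthConfig", "generate_recording", "generate_cohort",
           "write_cohort", "read_manifest"]

#: canonical EEG rhythm bands used by the generator (Hz)
GENERATOR_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}


@dataclass
class ClassEffect:
    """Per-class generator parameters.

    ``band_amps`` maps band name -> RMS amplitude of that band's
    oscillation, either a scalar (all channels) or one value per channel.
    ``pink_exponent`` is the 1/f^alpha slope of the background,
    ``pink_rms`` its RMS amplitude, ``noise_rms`` the white-noise floor,
    and ``ar_coef`` the AR(1) smoothing coefficient controlling temporal
    regularity (0 = none; higher -> smoother, lower entropy).
    """

    band_amps: dict[str, float | list[float]] = field(
        default_factory=lambda: {"delta": 8.0, "theta": 6.0, "alpha": 10.0, "beta": 4.0}
    )
    pink_exponent: float = 1.0
    pink_rms: float = 10.0
    noise_rms: float = 3.0
    ar_coef: float = 0.0

    def amp_for(self, band: str, channel_index: int, n_channels: int) -> float:
        amp = self.band_amps.get(band, 0.0)
        if np.isscalar(amp):
            return float(amp)  # type: ignore[arg-type]
        amp = list(amp)  # type: ignore[arg-type]
        if len(amp) != n_channels:
            raise ConfigError(
                f"band {band!r}: {len(amp)} amplitudes for {n_channels} channels"
            )
        return float(amp[channel_index])


def default_effects() -> dict[int, ClassEffect]:
    """Default class effects: patients (label 1) have ~1.8x beta amplitude
    and stronger AR(1) smoothing (lower permutation entropy / complexity)."""
    control = ClassEffect(ar_coef=0.05)
    patient = ClassEffect(
        band_amps={"delta": 8.0, "theta": 6.0, "alpha": 9.0, "beta": 7.2},
        ar_coef=0.35,
    )
    return {0: control, 1: patient}


@dataclass
class SynthConfig:
    """Configuration of a synthetic two-class EEG cohort.

    Defaults mirror a 34-patient / 30-control eyes-closed resting cohort
    with three prefrontal channels and 5-minute recordings at 256 Hz.
    """

    n_subjects_pos: int = 34
    n_subjects_neg: int = 30
    channels: tuple[str, ...] = ("Fp1", "Fz", "Fp2")
    fs: float = 256.0
    duration_s: float = 300.0
    seed: int = 0
    effect: dict[int, ClassEffect] = field(default_factory=default_effects)

    def __post_init__(self) -> None:
        if self.n_subjects_pos < 1 or self.n_subjects_neg < 1:
            raise ConfigError("need at least one subject per class")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ConfigError("fs and duration_s must be positive")
        top = max(hi for _, hi in GENERATOR_BANDS.values())
        if self.fs <= 2 * top:
            raise ConfigError(
                f"fs={self.fs} must exceed twice the highest generated band "
                f"frequency ({top} Hz)"
            )
        for lab in (0, 1):
            if lab not in self.effect:
                raise ConfigError(f"effect parameters missing for class {lab}")


def _subject_rng(config: SynthConfig, subject_id: str, label: int) -> np.random.Generator:
    # stream keyed on (seed, crc32(subject_id), label): stable across runs
    return np.random.default_rng(
        [int(config.seed), zlib.crc32(subject_id.encode()), int(label)]
    )


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """1/f^exponent noise with unit RMS, via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _ou_envelope(rng: np.random.Generator, n: int, fs: float,
                 tau_s: float = 2.0, sigma: float = 0.35) -> np.ndarray:
    """Positive, slowly drifting amplitude envelope (mean ~1).

    Ornstein-Uhlenbeck process around 1 with relaxation time ``tau_s``,
    clipped at 0.05 so the oscillation never vanishes entirely.
    """
    from scipy.signal import lfilter

    dt = 1.0 / fs
    a = np.exp(-dt / tau_s)
    innov_sd = sigma * np.sqrt(1.0 - a * a)
    steps = rng.standard_normal(n) * innov_sd
    env = lfilter([1.0], [1.0, -a], steps)  # AR(1) recursion, vectorized
    return np.clip(1.0 + env, 0.05, None)


def generate_recording(subject_id: str, label: int, config: SynthConfig) -> Recording:
    """Generate one subject's recording; pure function of (seed, id, label)."""
    if label not in (0, 1):
        raise ConfigError(f"label must be 0 or 1, got {label!r}")
    n = int(round(config.fs * config.duration_s))
    if n < 2:
        raise ConfigError("duration too short")
    eff = config.effect[label]
    rng = _subject_rng(config, subject_id, label)
    n_ch = len(config.channels)
    samples = np.empty((n_ch, n))
    t = np.arange(n) / config.fs
    for ci in range(n_ch):
        x = eff.pink_rms * _pink_noise(rng, n, eff.pink_exponent)
        for band, (lo, hi) in GENERATOR_BANDS.items():
            amp = eff.amp_for(band, ci, n_ch)
            if amp <= 0:
                continue
            f0 = rng.uniform(lo, hi)
            phase = rng.uniform(0, 2 * np.pi)
            env = _ou_envelope(rng, n, config.fs)
            # sqrt(2)*amp peak gives RMS ~= amp for a unit envelope
            x = x + np.sqrt(2.0) * amp * env * np.sin(2 * np.pi * f0 * t + phase)
        x = x + eff.noise_rms * rng.standard_normal(n)
        if eff.ar_coef != 0.0:
            from scipy.signal import lfilter

            sd_before = x.std()
            x = lfilter([1.0], [1.0, -eff.ar_coef], x)
            sd_after = x.std()
            if sd_after > 0:  # preserve overall amplitude scale
                x = x * (sd_before / sd_after)
        samples[ci] = x
    return Recording(
        subject_id=subject_id,
        label=int(label),
        channel_names=list(config.channels),
        fs=config.fs,
        samples=samples,
    )


def cohort_subject_ids(config: SynthConfig) -> list[tuple[str, int]]:
    """(subject_id, label) pairs: patients first, then controls."""
    out = [(f"mdd-{i + 1:03d}", 1) for i in range(config.n_subjects_pos)]
    out += [(f"hc-{i + 1:03d}", 0) for i in range(config.n_subjects_neg)]
    return out


def generate_cohort(config: SynthConfig) -> list[Recording]:
    """Generate the full cohort (n_subjects_pos + n_subjects_neg recordings)."""
    return [generate_recording(sid, lab, config) for sid, lab in cohort_subject_ids(config)]


# ---------------------------------------------------------------------------
# on-disk cohort: one NPZ per subject + a manifest CSV


def write_recording_npz(rec: Recording, path: Path) -> None:
    np.savez(
        path,
        samples=rec.samples,
        fs=np.array(rec.fs),
        channel_names=np.array(rec.channel_names),
        subject_id=np.array(rec.subject_id),
        label=np.array(rec.label),
    )


def write_cohort(recordings: list[Recording], outdir: Path) -> Path:
    """Write one NPZ per recording plus ``manifest.csv``; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "label", "file"])
        for rec in recordings:
            fname = f"{rec.subject_id}.npz"
            write_recording_npz(rec, outdir / fname)
            writer.writerow([rec.subject_id, rec.label, fname])
    return manifest


def read_manifest(manifest: Path) -> list[dict]:
    """Rows of a cohort manifest as dicts with resolved file paths."""
    manifest = Path(manifest)
    rows = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            row["label"] = int(row["label"])
            row["path"] = str(manifest.parent / row["file"])
            rows.append(row)
    return rows


def effects_from_dict(d: dict) -> dict[int, ClassEffect]:
    """Build the per-class effect map from a plain (e.g. YAML) dict."""
    out = {}
    for key, val in d.items():
        out[int(key)] = ClassEffect(**val)
    return out


def null_effects() -> dict[int, ClassEffect]:
    """Identical parameters for both classes (no planted effect)."""
    return {0: ClassEffect(ar_coef=0.15), 1: ClassEffect(ar_coef=0.15)}


def config_to_json(config: SynthConfig) -> str:
    d = {
        "n_subjects_pos": config.n_subjects_pos,
        "n_subjects_neg": config.n_subjects_neg,
        "channels": list(config.channels),
        "fs": config.fs,
        "duration_s": config.duration_s,
        "seed": config.seed,
        "effect": {
            str(k): {
                "band_amps": v.band_amps,
                "pink_exponent": v.pink_exponent,
                "pink_rms": v.pink_rms,
                "noise_rms": v.noise_rms,
                "ar_coef": v.ar_coef,
            }
            for k, v in config.effect.items()
        },
    }
    return json.dumps(d, indent=2)
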