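"""Core in-memory containers shared across the pipeline.

A :class:`Recording` is one subject's continuous multichannel EEG.  A
:class:`EpochSet` holds the fixed-length windows cut from one or more
recordings; it is the unit of feature extraction.  A
:class:`FeatureMatrix` is the epochs x named-features table that feature
selection and classification operate on.

All containers carry subject identifiers and the binary class label
(1 = patient / positive, 0 = control / negative) so that downstream
cross-validation can group by subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["Recording", "EpochSet", "FeatureMatrix"]


@dataclass
class Recording:
    """One subject's continuous multichannel EEG.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    label : int
        Binary class label, 1 for the positive (patient) class.
    channel_names : list of str
        Electrode names, one per row of ``samples``.
    fs : float
        Sampling rate in Hz.
    samples : ndarray, shape (n_channels, n_samples)
        Signal values (arbitrary amplitude units, typically microvolts).
    """

    subject_id: str
    label: int
    channel_names: list[str]
    fs: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise DataError("samples must be a 2-D (channels x time) array")
        if len(self.channel_names) != self.samples.shape[0]:
            raise DataError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} signal rows"
            )
        if self.fs <= 0:
            raise DataError("sampling rate must be positive")
        if self.label not in (0, 1):
            raise DataError(f"label must be 0 or 1, got {self.label!r}")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray) -> "Recording":
        """Copy of this recording with new signal values, metadata unchanged."""
        return replace(self, samples=samples)

    def pick_channels(self, channels: list[str]) -> "Recording":
        """Restrict to ``channels`` in the requested order."""
        missing = [c for c in channels if c not in self.channel_names]
        if missing:
            raise DataError(f"requested channels not present: {missing}")
        idx = [self.channel_names.index(c) for c in channels]
        return replace(self, channel_names=list(channels), samples=self.samples[idx])


@dataclass
class EpochSet:
    """Fixed-length windows cut from recordings.

    ``epochs`` has shape (n_epochs, n_channels, window_samples); every epoch
    carries the subject id and label of the recording it was cut from.
    """

    epochs: np.ndarray
    subject_ids: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str]
    window_s: float
    step_s: float

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.epochs.ndim != 3:
            raise DataError("epochs must be (n_epochs, n_channels, n_samples)")
        n = self.epochs.shape[0]
        if n < 1:
            raise DataError("EpochSet must contain at least one epoch")
        if len(self.subject_ids) != n or len(self.labels) != n:
            raise DataError("subject_ids/labels length must match epoch count")
        # one label per subject
        per_subject: dict[str, int] = {}
        for sid, lab in zip(self.subject_ids, self.labels):
            if per_subject.setdefault(str(sid), int(lab)) != int(lab):
                raise DataError(f"subject {sid!r} appears with two labels")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def to_npz(self, path) -> None:
        np.savez(
            path,
            epochs=self.epochs,
            subject_ids=self.subject_ids.astype(str),
            labels=self.labels,
            fs=np.array(self.fs),
            channel_names=np.array(self.channel_names),
            window_s=np.array(self.window_s),
            step_s=np.array(self.step_s),
        )

    @classmethod
    def from_npz(cls, path) -> "EpochSet":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                epochs=z["epochs"],
                subject_ids=z["subject_ids"],
                labels=z["labels"],
                fs=float(z["fs"]),
                channel_names=[str(c) for c in z["channel_names"]],
                window_s=float(z["window_s"]),
                step_s=float(z["step_s"]),
            )

    @staticmethod
    def concatenate(parts: list["EpochSet"]) -> "EpochSet":
        """Stack epoch sets from several recordings (same geometry required)."""
        if not parts:
            raise DataError("nothing to concatenate")
        first = parts[0]
        for p in parts[1:]:
            if (
                p.fs != first.fs
                or p.channel_names != first.channel_names
                or p.window_s != first.window_s
                or p.step_s != first.step_s
            ):
                raise DataError("epoch sets have incompatible geometry")
        return EpochSet(
            epochs=np.concatenate([p.epochs for p in parts], axis=0),
            subject_ids=np.concatenate([p.subject_ids for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            fs=first.fs,
            channel_names=first.channel_names,
            window_s=first.window_s,
            step_s=first.step_s,
        )


@dataclass
class FeatureMatrix:
    """Epochs x named features, with per-epoch subject ids and labels.

    Feature names follow the ``<Measure>_<Channel>`` convention, e.g.
    ``BetaPower_Fp1`` or ``HjorthComplexity_Fz``.
    """

    values: np.ndarray
    feature_names: list[str]
    subject_ids: np.ndarray
    labels: np.ndarray
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise DataError("feature values must be 2-D (epochs x features)")
        if self.values.shape[1] != len(self.feature_names):
            raise DataError("feature_names length must match column count")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise DataError("feature names must be unique")
        if len(self.subject_ids) != self.values.shape[0]:
            raise DataError("subject_ids length must match row count")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    def select_columns(self, indices: np.ndarray) -> "FeatureMatrix":
        indices = np.asarray(indices)
        return FeatureMatrix(
            values=self.values[:, indices],
            feature_names=[self.feature_names[i] for i in indices],
            subject_ids=self.subject_ids,
            labels=self.labels,
        )

    def select_rows(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values[mask],
            feature_names=list(self.feature_names),
            subject_ids=self.subject_ids[mask],
            labels=self.labels[mask],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureMatrix":
        if "subject_id" not in df.columns or "label" not in df.columns:
            raise DataError("feature table needs 'subject_id' and 'label' columns")
        names = [c for c in df.columns if c not in ("subject_id", "label")]
        return cls(
            values=df[names].to_numpy(dtype=float),
            feature_names=names,
            subject_ids=df["subject_id"].to_numpy(),
            labels=df["label"].to_numpy(dtype=int),
        )

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        return cls.from_dataframe(pd.read_csv(path))

    def to_npz(self, path) -> None:
        np.savez(
            path,
            values=self.values,
            feature_names=np.array(self.feature_names),
            subject_ids=self.subject_ids.astype(str),
            labels=self.labels,
        )

    @classmethod
    def from_npz(cls, path) -> "FeatureMatrix":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                values=z["values"],
                feature_names=[str(s) for s in z["feature_names"]],
                subject_ids=z["subject_ids"],
                labels=z["labels"],
            )
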