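"""Core in-memory containers for continuous recordings and epoched data.

A :class:`Recording` is a continuous multi-channel EEG signal (channels x
samples, microvolts) with its sampling rate and montage labels.  An
:class:`EpochSet` holds fixed-length windows cut from one or more recordings
(epochs x channels x samples) plus optional per-epoch class labels.

Both containers serialize to an uncompressed ``.npz`` archive with the
metadata (sampling rate, labels, window geometry) stored alongside the
arrays, so fixtures are plain, portable files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Recording", "EpochSet"]


@dataclass
class Recording:
    """Continuous multi-channel EEG.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique montage labels (e.g. 10-20 names), one per channel.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x samples) array")
        c, n = self.samples.shape
        if c < 1 or n < 1:
            raise ValueError("recording needs at least one channel and one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"EEG{i:03d}" for i in range(c)]
        if len(self.channel_labels) != c:
            raise ValueError("need exactly one label per channel")
        if len(set(self.channel_labels)) != c:
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return Recording(self.samples.copy(), self.fs, list(self.channel_labels))

    def save_npz(self, path) -> None:
        meta = json.dumps({"fs": self.fs, "channel_labels": self.channel_labels})
        np.savez(path, samples=self.samples, meta=np.array(meta))

    @classmethod
    def load_npz(cls, path) -> "Recording":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            return cls(f["samples"], meta["fs"], meta["channel_labels"])


@dataclass
class EpochSet:
    """Fixed-length labeled windows: epochs x channels x samples."""

    epochs: np.ndarray
    fs: float
    window_s: float
    start_times: np.ndarray
    labels: np.ndarray | None = None
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be a 3-D (epochs x channels x samples) array")
        self.start_times = np.asarray(self.start_times, dtype=np.float64)
        if self.start_times.shape != (self.n_epochs,):
            raise ValueError("need one start time per epoch")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (self.n_epochs,):
                raise ValueError("labels must have one entry per epoch")
        if not self.channel_labels:
            self.channel_labels = [f"EEG{i:03d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("need exactly one label per channel")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    def subset(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(
            self.epochs[idx],
            self.fs,
            self.window_s,
            self.start_times[idx],
            None if self.labels is None else self.labels[idx],
            list(self.channel_labels),
        )

    def save_npz(self, path) -> None:
        meta = json.dumps(
            {
                "fs": self.fs,
                "window_s": self.window_s,
                "channel_labels": self.channel_labels,
                "has_labels": self.labels is not None,
            }
        )
        arrays = {
            "epochs": self.epochs,
            "start_times": self.start_times,
            "meta": np.array(meta),
        }
        if self.labels is not None:
            arrays["labels"] = np.asarray(self.labels)
        np.savez(path, **arrays)

    @classmethod
    def load_npz(cls, path) -> "EpochSet":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            labels = f["labels"] if meta["has_labels"] else None
            return cls(
                f["epochs"],
                meta["fs"],
                meta["window_s"],
                f["start_times"],
                labels,
                meta["channel_labels"],
            )
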