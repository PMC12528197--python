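"""Band-power features and frame tokenization.

Band powers integrate a Welch PSD estimate over the five canonical EEG
bands per (epoch, channel); optionally normalized to relative power.
Framing tiles each epoch-channel into contiguous frames — the token
sequence fed to the temporal attention stack — either as raw sample
vectors or as per-frame 5-band power vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .containers import EpochSet
from .synth import BANDS

__all__ = ["BAND_EDGES", "BandPowerTable", "FrameSequence", "band_powers", "frame"]

#: ((low, high), ...) in canonical order delta/theta/alpha/beta/gamma
BAND_EDGES = tuple(BANDS.values())
BAND_NAMES = tuple(BANDS)


@dataclass
class BandPowerTable:
    """Per-epoch, per-channel power in the five canonical bands."""

    powers: np.ndarray  # E x C x 5
    band_edges: tuple = BAND_EDGES
    normalization: str = "none"  # or "relative"
    channel_labels: list | None = None

    def to_csv(self, path, epoch: int = 0) -> None:
        """One epoch as CSV: channel rows, one column per band."""
        labels = self.channel_labels or [
            f"Channel {i + 1}" for i in range(self.powers.shape[1])
        ]
        header = "EEG channel," + ",".join(
            f"{name.capitalize()} ({lo}-{hi} Hz)"
            for name, (lo, hi) in zip(BAND_NAMES, self.band_edges)
        )
        rows = [header]
        for ch, lab in enumerate(labels):
            vals = ",".join(f"{v:.6g}" for v in self.powers[epoch, ch])
            rows.append(f"{lab},{vals}")
        with open(path, "w") as f:
            f.write("\n".join(rows) + "\n")


@dataclass
class FrameSequence:
    """Tokens per epoch and channel: E x C x P x frame_dim."""

    frames: np.ndarray
    frame_length: int  # samples per frame in the source epoch
    layout: str  # "raw_frames" | "band_frames"

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]

    @property
    def frame_dim(self) -> int:
        return self.frames.shape[3]


def _band_power_matrix(x: np.ndarray, fs: float, edges) -> np.ndarray:
    """Integrate Welch PSD over bands; x has samples on the last axis."""
    n = x.shape[-1]
    nperseg = min(n, 256)
    f, psd = _sig.welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2, axis=-1)
    out = np.empty(x.shape[:-1] + (len(edges),))
    for b, (lo, hi) in enumerate(edges):
        m = (f >= lo) & (f <= hi)
        if m.sum() < 2:
            # too few bins to integrate: take the nearest-bin PSD mass
            m = np.zeros_like(m)
            m[np.argmin(np.abs(f - (lo + hi) / 2))] = True
            out[..., b] = psd[..., m].sum(axis=-1) * (hi - lo)
        else:
            out[..., b] = np.trapezoid(psd[..., m], f[m], axis=-1)
    return out


def band_powers(
    epochs: EpochSet, edges=BAND_EDGES, normalize: bool = False
) -> BandPowerTable:
    """Welch band powers per (epoch, channel).

    Uses segment length min(L, 256) with 50% overlap; band power is the
    trapezoidal integral of the PSD between the band edges.  With
    ``normalize=True`` the five values per (epoch, channel) sum to one.
    Note that 2-s epochs give coarse resolution in the delta band (0.5 Hz
    lower edge); the estimate is still computed.
    """
    if epochs.n_epochs == 0:
        raise ValueError("empty EpochSet")
    for lo, hi in edges:
        if hi > epochs.fs / 2:
            raise ValueError(f"band edge {hi} Hz above Nyquist ({epochs.fs / 2})")
    p = _band_power_matrix(epochs.epochs, epochs.fs, edges)
    if normalize:
        tot = p.sum(axis=-1, keepdims=True)
        p = np.divide(p, tot, out=np.zeros_like(p), where=tot > 0)
    return BandPowerTable(
        p, tuple(edges), "relative" if normalize else "none",
        list(epochs.channel_labels),
    )


def frame(epochs: EpochSet, n_frames: int = 16, layout: str = "raw_frames") -> FrameSequence:
    """Tile each epoch-channel into ``n_frames`` contiguous tokens.

    ``raw_frames`` keeps the samples (frame_dim = L / n_frames);
    ``band_frames`` replaces each frame by its 5-band power vector,
    estimated from the frame's periodogram.
    """
    e, c, length = epochs.epochs.shape
    if length % n_frames != 0:
        raise ValueError(f"epoch length {length} not divisible by n_frames={n_frames}")
    flen = length // n_frames
    tiles = epochs.epochs.reshape(e, c, n_frames, flen)
    if layout == "raw_frames":
        return FrameSequence(tiles, flen, layout)
    if layout == "band_frames":
        powers = _band_power_matrix(tiles, epochs.fs, BAND_EDGES)
        # log compression stabilizes scale across bands
        return FrameSequence(np.log1p(powers), flen, layout)
    raise ValueError(f"unknown layout {layout!r}")
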