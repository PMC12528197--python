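"""Synthetic multi-channel EEG with known ground truth.

The generator emulates a 64-channel, 256 Hz acquisition over the 10-20
electrode layout.  Each class is defined by a band-power signature: one
band-limited Gaussian source per canonical band (delta/theta/alpha/beta/
gamma), with source amplitude set by the class's relative band weight.
Sources are mixed into channels by a random full-rank matrix, after which
eye-blink-like low-frequency transients (frontal channels, Poisson
arrivals), a sustained mains sinusoid, and additive Gaussian sensor noise
can be layered on.  Every output is a pure function of (spec, seed).

"X% Gaussian noise" is defined throughout as added noise whose standard
deviation is X% of the clean signal's per-channel standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .containers import EpochSet, Recording

__all__ = [
    "BANDS",
    "SynthSpec",
    "GroundTruth",
    "generate_recording",
    "add_gaussian_noise",
    "add_gaussian_noise_epochs",
    "make_classification_task",
    "ten_twenty_labels",
]

#: canonical EEG frequency bands (Hz)
BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 50.0),
}

_BAND_ORDER = tuple(BANDS)

# 64 electrode names from the extended 10-20 (10-10) layout
_TEN_TWENTY_64 = (
    "Fp1 Fpz Fp2 AF7 AF3 AFz AF4 AF8 F7 F5 F3 F1 Fz F2 F4 F6 F8 "
    "FT7 FC5 FC3 FC1 FCz FC2 FC4 FC6 FT8 T7 C5 C3 C1 Cz C2 C4 C6 T8 "
    "TP7 CP5 CP3 CP1 CPz CP2 CP4 CP6 TP8 P7 P5 P3 P1 Pz P2 P4 P6 P8 "
    "PO7 PO5 PO3 POz PO4 PO6 PO8 O1 Oz O2 Iz"
).split()


def ten_twenty_labels(n_channels: int) -> list[str]:
    """Montage labels: 10-20 names when n <= 64, generic beyond."""
    if n_channels <= len(_TEN_TWENTY_64):
        return list(_TEN_TWENTY_64[:n_channels])
    return list(_TEN_TWENTY_64) + [
        f"EEG{i:03d}" for i in range(len(_TEN_TWENTY_64), n_channels)
    ]


def _default_signatures() -> dict[str, dict[str, float]]:
    # alpha-dominant vs theta-dominant: separable in band-power space
    return {
        "alpha": {"delta": 0.10, "theta": 0.10, "alpha": 1.00, "beta": 0.15, "gamma": 0.05},
        "theta": {"delta": 0.10, "theta": 1.00, "alpha": 0.10, "beta": 0.15, "gamma": 0.05},
    }


@dataclass
class SynthSpec:
    """Parameters of the synthetic acquisition.

    Defaults follow the emulated recording regime: 64 channels at 256 Hz,
    eye blinks at a typical spontaneous rate, mild mains contamination and
    no extra sensor noise (noise sweeps are applied at evaluation time).
    """

    n_channels: int = 64
    fs: float = 256.0
    duration_s: float = 10.0
    n_recordings: int = 1
    class_signatures: dict[str, dict[str, float]] = field(default_factory=_default_signatures)
    artifact_rate: float = 12.0  # expected blink events per minute
    line_noise_hz: float = 50.0
    line_noise_amp: float = 0.2  # mains amplitude relative to channel SD; 0 disables
    noise_sigma_pct: float = 0.0  # additive Gaussian noise, % of channel SD
    background_amp: float = 0.01  # rank-filling broadband sources, relative SD
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        top = max(hi for _, hi in BANDS.values())
        if self.fs <= 2 * top:
            raise ValueError(f"fs={self.fs} below Nyquist for bands up to {top} Hz")
        if self.artifact_rate < 0 or self.noise_sigma_pct < 0:
            raise ValueError("rates and noise percentages must be non-negative")
        if not self.class_signatures:
            raise ValueError("class_signatures must not be empty")
        for cls, sig in self.class_signatures.items():
            for band, w in sig.items():
                if band not in BANDS:
                    raise ValueError(f"unknown band {band!r} in class {cls!r}")
                if w < 0:
                    raise ValueError(f"negative band weight for {cls!r}/{band}")


@dataclass
class GroundTruth:
    """What the generator actually did — the oracle for downstream tests."""

    class_label: str
    mixing: np.ndarray  # channels x sources, square full rank
    clean: Recording  # pre-artifact, pre-noise mixture
    artifact_times: np.ndarray  # blink onsets, seconds
    artifact_channels: list[int]  # frontal channel indices carrying blinks


def _bandlimited_noise(rng, n, fs, lo, hi):
    """Unit-SD Gaussian noise band-limited to [lo, hi] Hz."""
    x = rng.standard_normal(n)
    sos = _sig.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = _sig.sosfiltfilt(sos, x)
    return y / max(y.std(), 1e-12)


def generate_recording(
    spec: SynthSpec, class_label: str, seed: int | None = None
) -> tuple[Recording, GroundTruth]:
    """Generate one labeled recording plus its ground truth.

    The recording is a random full-rank channel mixture of one narrowband
    source per canonical band (amplitude = sqrt of the class's band
    weight) plus low-amplitude broadband sources that complete the square
    source matrix, with artifacts and noise added per spec.
    """
    spec.validate()
    if class_label not in spec.class_signatures:
        raise KeyError(f"unknown class label {class_label!r}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    c = spec.n_channels
    n = int(round(spec.duration_s * spec.fs))
    sig = spec.class_signatures[class_label]

    # --- square source matrix: 5 band sources, then broadband fillers
    n_band = min(len(_BAND_ORDER), c)
    sources = np.zeros((c, n))
    for k, band in enumerate(_BAND_ORDER[:n_band]):
        w = sig.get(band, 0.0)
        src = _bandlimited_noise(rng, n, spec.fs, *BANDS[band])
        sources[k] = np.sqrt(w) * src
    for k in range(n_band, c):
        sources[k] = spec.background_amp * _bandlimited_noise(rng, n, spec.fs, 0.5, 50.0)

    # --- full-rank mixing; band-source columns bounded away from zero so
    # every channel carries every active band
    mixing = rng.standard_normal((c, c))
    band_cols = rng.uniform(0.5, 1.5, size=(c, n_band)) * rng.choice([-1.0, 1.0], size=(c, n_band))
    mixing[:, :n_band] = band_cols
    while np.linalg.matrix_rank(mixing) < c:  # pragma: no cover - prob. 0
        mixing = rng.standard_normal((c, c))
        mixing[:, :n_band] = band_cols
    x = mixing @ sources

    clean = Recording(x.copy(), spec.fs, ten_twenty_labels(c))
    sd = x.std(axis=1)

    # --- eye-blink proxies: Poisson arrivals of <4 Hz transients, frontal
    frontal = [i for i, lab in enumerate(clean.channel_labels) if lab[:2] in ("Fp", "AF")]
    if not frontal:
        frontal = list(range(max(1, c // 4)))
    n_events = rng.poisson(spec.artifact_rate * spec.duration_s / 60.0)
    width = int(round(0.4 * spec.fs))
    blink = np.hanning(width)
    times = np.sort(rng.uniform(0, spec.duration_s, size=n_events))
    for t0 in times:
        i0 = int(t0 * spec.fs)
        i1 = min(i0 + width, n)
        for ch in frontal:
            amp = 8.0 * sd[ch] * rng.uniform(0.7, 1.3)
            x[ch, i0:i1] += amp * blink[: i1 - i0]

    # --- sustained mains sinusoid
    if spec.line_noise_amp > 0:
        t = np.arange(n) / spec.fs
        phase = rng.uniform(0, 2 * np.pi)
        x += spec.line_noise_amp * sd[:, None] * np.sin(2 * np.pi * spec.line_noise_hz * t + phase)

    # --- additive Gaussian sensor noise
    if spec.noise_sigma_pct > 0:
        x += (spec.noise_sigma_pct / 100.0) * sd[:, None] * rng.standard_normal(x.shape)

    rec = Recording(x, spec.fs, list(clean.channel_labels))
    gt = GroundTruth(class_label, mixing, clean, times, frontal)
    return rec, gt


def add_gaussian_noise(rec: Recording, pct: float, seed: int) -> Recording:
    """Add zero-mean Gaussian noise at ``pct`` % of each channel's SD."""
    if pct < 0:
        raise ValueError("noise percentage must be non-negative")
    if pct == 0:
        return rec.copy()
    rng = np.random.default_rng(seed)
    sd = rec.samples.std(axis=1, keepdims=True)
    noisy = rec.samples + (pct / 100.0) * sd * rng.standard_normal(rec.samples.shape)
    return Recording(noisy, rec.fs, list(rec.channel_labels))


def add_gaussian_noise_epochs(epochs: EpochSet, pct: float, seed: int) -> EpochSet:
    """Same noise rule applied per (epoch, channel) to an EpochSet."""
    if pct < 0:
        raise ValueError("noise percentage must be non-negative")
    if pct == 0:
        out = epochs.subset(np.arange(epochs.n_epochs))
        return out
    rng = np.random.default_rng(seed)
    sd = epochs.epochs.std(axis=2, keepdims=True)
    noisy = epochs.epochs + (pct / 100.0) * sd * rng.standard_normal(epochs.epochs.shape)
    return EpochSet(
        noisy, epochs.fs, epochs.window_s, epochs.start_times, epochs.labels,
        list(epochs.channel_labels),
    )


def make_classification_task(
    n_epochs_per_class: int = 200,
    n_channels: int = 8,
    fs: float = 256.0,
    window_s: float = 2.0,
    classes: tuple[str, ...] = ("alpha", "theta"),
    signatures: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
) -> EpochSet:
    """Build a labeled EpochSet for the synthetic classification task.

    One long clean recording per class (no artifacts or mains — noise
    robustness is probed separately at evaluation time), cut into
    non-overlapping windows.  Deterministic in ``seed``.
    """
    from .preprocessing import segment

    spec = SynthSpec(
        n_channels=n_channels,
        fs=fs,
        duration_s=n_epochs_per_class * window_s,
        class_signatures=signatures or _default_signatures(),
        artifact_rate=0.0,
        line_noise_amp=0.0,
        noise_sigma_pct=0.0,
    )
    if signatures is None:
        missing = [c for c in classes if c not in spec.class_signatures]
        if missing:
            raise KeyError(f"no default signature for classes {missing}")
    seeds = np.random.SeedSequence(seed).generate_state(len(classes)) % (2**31)
    parts, labels = [], []
    for cls, s in zip(classes, seeds):
        rec, _ = generate_recording(spec, cls, seed=int(s))
        es = segment(rec, window_s=window_s)
        parts.append(es.epochs)
        labels.extend([cls] * es.n_epochs)
    epochs = np.concatenate(parts, axis=0)
    starts = np.arange(len(labels)) * window_s
    return EpochSet(
        epochs, fs, window_s, starts, np.array(labels), ten_twenty_labels(n_channels)
    )
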