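"""Signal conditioning: ICA artifact removal, band-pass filtering, epoching.

The observed channels are modeled as an instantaneous linear mixture
``X = A S`` of independent sources; FastICA estimates the unmixing by
fixed-point maximization of non-Gaussianity.  Components dominated by
high kurtosis or by sub-4 Hz power (eye-blink signatures) are zeroed and
the recording is rebuilt from the censored sources.  Filtering is a
zero-phase Butterworth band-pass (default 0.5-50 Hz, order 6), and
segmentation cuts fixed-length windows with optional overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig
from scipy import stats as _stats
from sklearn.decomposition import FastICA

from .containers import EpochSet, Recording

__all__ = [
    "FilterSpec",
    "ICAResult",
    "run_ica",
    "reject_artifact_components",
    "bandpass",
    "segment",
    "preprocess",
]


@dataclass
class FilterSpec:
    """Band-pass specification.

    Order 6 (forward-backward, so the effective magnitude response is
    squared) keeps a 50 Hz upper edge while pushing a 60 Hz mains tone
    below 10% amplitude; lower orders do not reach that rejection.
    """

    low_hz: float = 0.5
    high_hz: float = 50.0
    order: int = 6
    family: str = "butterworth"

    def validate(self, fs: float) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.high_hz >= fs / 2:
            raise ValueError(f"high_hz={self.high_hz} at or above Nyquist ({fs / 2})")
        if self.family not in ("butterworth", "fir-window"):
            raise ValueError(f"unknown filter family {self.family!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass
class ICAResult:
    """Decomposition X = mixing @ sources (+ channel means)."""

    mixing: np.ndarray  # C x C
    unmixing: np.ndarray  # C x C
    sources: np.ndarray  # C x N
    mean: np.ndarray  # per-channel mean removed before unmixing
    fs: float
    channel_labels: list[str]
    converged: bool
    rejected_components: list[int] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]

    def reconstruct(self) -> Recording:
        """Recording rebuilt from sources with rejected components zeroed."""
        s = self.sources.copy()
        if self.rejected_components:
            s[self.rejected_components] = 0.0
        x = self.mixing @ s + self.mean[:, None]
        return Recording(x, self.fs, list(self.channel_labels))

    @property
    def cleaned(self) -> Recording:
        return self.reconstruct()


def run_ica(
    rec: Recording, seed: int = 0, max_iter: int = 500, tol: float = 1e-5
) -> ICAResult:
    """Decompose a recording into independent components (FastICA).

    Deterministic given ``seed``.  Raises on rank-deficient input; a run
    that does not converge within ``max_iter`` returns the partial result
    with ``converged=False``.
    """
    c, n = rec.samples.shape
    if n < 10 * c:
        raise ValueError(f"need at least 10 samples per channel^2 ({n} < {10 * c})")
    centered = rec.samples - rec.samples.mean(axis=1, keepdims=True)
    cov = (centered @ centered.T) / n
    if np.linalg.matrix_rank(cov, tol=1e-10 * max(1.0, np.trace(cov))) < c:
        raise np.linalg.LinAlgError("rank-deficient input: channels are linearly dependent")

    ica = FastICA(
        n_components=c, random_state=seed, max_iter=max_iter, tol=tol,
        whiten="unit-variance",
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        sources = ica.fit_transform(rec.samples.T).T  # C x N
        if any("did not converge" in str(w.message) for w in caught):
            converged = False
    return ICAResult(
        mixing=ica.mixing_,
        unmixing=ica.components_,
        sources=sources,
        mean=ica.mean_,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        converged=converged,
    )


def _low_freq_fraction(source: np.ndarray, fs: float, cutoff_hz: float = 4.0) -> float:
    f, p = _sig.welch(source, fs=fs, nperseg=min(len(source), 1024))
    total = np.trapezoid(p, f)
    if total <= 0:
        return 0.0
    mask = f <= cutoff_hz
    return float(np.trapezoid(p[mask], f[mask]) / total)


def reject_artifact_components(
    ica: ICAResult,
    kurtosis_threshold: float = 5.0,
    low_freq_fraction_threshold: float = 0.6,
) -> ICAResult:
    """Flag artifact components and return a result with them zeroed.

    A component is flagged when its excess kurtosis exceeds the threshold
    (spiky transients such as blinks) or when more than the given fraction
    of its power lies below 4 Hz (slow ocular drift).  Refuses to flag
    every component, which would erase the signal.
    """
    flagged = []
    for k in range(ica.n_components):
        s = ica.sources[k]
        if _stats.kurtosis(s, fisher=True) > kurtosis_threshold:
            flagged.append(k)
        elif _low_freq_fraction(s, ica.fs) > low_freq_fraction_threshold:
            flagged.append(k)
    if len(flagged) == ica.n_components:
        raise ValueError("all components flagged as artifacts; refusing to erase the signal")
    return ICAResult(
        mixing=ica.mixing,
        unmixing=ica.unmixing,
        sources=ica.sources,
        mean=ica.mean,
        fs=ica.fs,
        channel_labels=list(ica.channel_labels),
        converged=ica.converged,
        rejected_components=flagged,
    )


def bandpass(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Zero-phase band-pass: forward-backward filtering, no phase shift."""
    spec = spec or FilterSpec()
    spec.validate(rec.fs)
    if rec.n_samples <= 3 * spec.order:
        raise ValueError("recording shorter than filter warm-up")
    if spec.family == "butterworth":
        sos = _sig.butter(
            spec.order, [spec.low_hz, spec.high_hz], btype="bandpass",
            fs=rec.fs, output="sos",
        )
        y = _sig.sosfiltfilt(sos, rec.samples, axis=1)
    else:  # fir-window
        ntaps = 2 * spec.order + 1
        taps = _sig.firwin(
            ntaps, [spec.low_hz, spec.high_hz], pass_zero=False, fs=rec.fs
        )
        y = _sig.filtfilt(taps, [1.0], rec.samples, axis=1)
    return Recording(y, rec.fs, list(rec.channel_labels))


def segment(rec: Recording, window_s: float, overlap_s: float = 0.0) -> EpochSet:
    """Cut fixed-length windows [t0, t0+T) with optional overlap.

    The trailing partial window is dropped; with zero overlap the epochs
    tile the retained portion of the recording exactly.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if not 0 <= overlap_s < window_s:
        raise ValueError("need 0 <= overlap_s < window_s")
    length = int(round(window_s * rec.fs))
    hop = int(round((window_s - overlap_s) * rec.fs))
    n = rec.n_samples
    if n < length:
        raise ValueError("recording shorter than one window")
    starts = np.arange(0, n - length + 1, hop)
    epochs = np.stack([rec.samples[:, s : s + length] for s in starts])
    return EpochSet(
        epochs, rec.fs, window_s, starts / rec.fs, None, list(rec.channel_labels)
    )


def preprocess(
    rec: Recording,
    filter_spec: FilterSpec | None = None,
    window_s: float = 2.0,
    overlap_s: float = 0.0,
    run_ica_step: bool = True,
    seed: int = 0,
) -> EpochSet:
    """Full conditioning chain: band-pass -> ICA rejection -> segmentation."""
    rec = bandpass(rec, filter_spec)
    if run_ica_step:
        ica = run_ica(rec, seed=seed)
        try:
            rec = reject_artifact_components(ica).cleaned
        except ValueError:
            rec = ica.cleaned  # nothing safely removable
    return segment(rec, window_s, overlap_s)
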