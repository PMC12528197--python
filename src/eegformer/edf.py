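"""EDF (European Data Format) export and import for :class:`Recording`.

Clinical EEG corpora are distributed as EDF, a fixed-layout ASCII-header
format carrying 16-bit integer samples.  Writing is implemented here
directly against the format layout; reading goes through :mod:`mne`, so the
round trip is checked by an independent reader.

Samples are quantized to the declared physical range: the round-trip error
is bounded by ``physical_range / 2**15`` per sample.
"""

from __future__ import annotations

import datetime

import numpy as np

from .containers import Recording

__all__ = ["write_edf", "read_edf"]

_DIG_MAX = 32767  # 16-bit signed, symmetric range


def _fit8(x: float, width: int = 8) -> str:
    """Format a number into at most ``width`` ASCII chars (EDF field)."""
    for prec in (8, 7, 6, 5, 4, 3, 2):
        s = f"{x:.{prec}g}"
        if len(s) <= width:
            return s
    raise ValueError(f"cannot format {x!r} into a {width}-character EDF field")


def write_edf(rec: Recording, path) -> None:
    """Write a recording as a single-data-record 16-bit EDF file.

    The physical range is set per channel to (just above) the channel's
    peak absolute amplitude, symmetric about zero, so quantization error
    is at most ``peak/2**15``.
    """
    if not np.all(np.isfinite(rec.samples)):
        raise ValueError("cannot write non-finite samples to EDF")
    c, n = rec.samples.shape
    duration = n / rec.fs

    # per-channel symmetric physical range; EDF needs pmin < pmax
    peaks = np.maximum(np.abs(rec.samples).max(axis=1), 1e-6)
    phys_max = []
    for p in peaks:
        # 7 chars so "-pm" also fits its field: min/max stay symmetric
        s = _fit8(float(p), width=7)
        # rounding in the fixed-width field must not clip the peak
        while float(s) < p:
            s = _fit8(float(s) * 1.001, width=7)
        phys_max.append(float(s))
    phys_max = np.array(phys_max)

    now = datetime.datetime(2000, 1, 1)
    header = (
        f"{'0':<8}"
        f"{'X X X X':<80}"
        f"{'Startdate 01-JAN-2000 X X X':<80}"
        f"{now:%d.%m.%y}"
        f"{now:%H.%M.%S}"
        f"{256 * (c + 1):<8}"
        f"{'':<44}"
        f"{1:<8}"
        f"{_fit8(duration):<8}"
        f"{c:<4}"
    )
    fields = [
        ("".join(f"{lab[:16]:<16}" for lab in rec.channel_labels)),
        ("".join(f"{'':<80}" for _ in range(c))),
        ("".join(f"{'uV':<8}" for _ in range(c))),
        ("".join(f"{_fit8(-pm):<8}" for pm in phys_max)),
        ("".join(f"{_fit8(pm):<8}" for pm in phys_max)),
        ("".join(f"{-_DIG_MAX:<8}" for _ in range(c))),  # symmetric: offset-free scaling
        ("".join(f"{_DIG_MAX:<8}" for _ in range(c))),
        ("".join(f"{'':<80}" for _ in range(c))),
        ("".join(f"{n:<8}" for _ in range(c))),
        ("".join(f"{'':<32}" for _ in range(c))),
    ]
    digital = np.rint(rec.samples / phys_max[:, None] * _DIG_MAX)
    digital = np.clip(digital, -_DIG_MAX, _DIG_MAX).astype("<i2")

    with open(path, "wb") as f:
        f.write(header.encode("ascii"))
        for block in fields:
            f.write(block.encode("ascii"))
        f.write(digital.tobytes())  # one record: channel-major


def read_edf(path) -> Recording:
    """Read an EDF file into a :class:`Recording` (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne works in volts
    return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names))
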