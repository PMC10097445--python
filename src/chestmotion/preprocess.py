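"""Windowing, gravity correction and spectral features.

The recognition pipeline works at 10 Hz on 2 s windows of 20 samples with 50%
overlap.  Each window is gravity-corrected by subtracting the per-axis mean
(the quasi-constant gravitational component) and Fourier transformed; the
classifier consumes the one-sided magnitude spectrum, an 11-bin x 3-axis
sequence with 0.5 Hz bins.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np

from .signal_synth import AccelStream

log = logging.getLogger(__name__)

DEFAULT_WIDTH = 20
DEFAULT_OVERLAP = 0.5
DEFAULT_RATE = 10.0

__all__ = [
    "WindowSlice",
    "FeatureSequence",
    "resample",
    "slice_windows",
    "gravity_correct",
    "spectral_features",
    "stream_to_features",
    "features_to_table",
    "table_to_features",
]


@dataclass
class WindowSlice:
    """A fixed-width slice of a stream: ``values`` is (width, 3) in m/s^2."""

    values: np.ndarray
    start_index: int
    rate: float
    label: str | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError(f"window values must be (width, 3), got {self.values.shape}")
        if self.start_index < 0:
            raise ValueError("start_index must be >= 0")

    @property
    def width(self) -> int:
        return self.values.shape[0]


@dataclass
class FeatureSequence:
    """One-sided DFT magnitude spectra: ``spectra`` is (bins, 3), bins = width//2 + 1."""

    spectra: np.ndarray
    bin_hz: float
    label: str | None = None
    subject_id: str | None = None
    start_index: int = 0

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        if np.any(self.spectra < 0):
            raise ValueError("spectral magnitudes must be non-negative")


def resample(stream: AccelStream, target_rate: float = DEFAULT_RATE) -> AccelStream:
    """Linearly interpolate a stream onto a uniform grid at ``target_rate``.

    Only downsampling (or pass-through at the same rate) is supported; the
    recordings arrive at 10-128 Hz and the pipeline works at 10 Hz.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if np.isclose(stream.rate, target_rate, rtol=1e-9):
        return stream
    if stream.rate < target_rate:
        raise ValueError(
            f"cannot upsample: stream rate {stream.rate} Hz < target {target_rate} Hz"
        )
    n_out = int(round(len(stream) * target_rate / stream.rate))
    t_new = stream.t[0] + np.arange(n_out) / target_rate
    t_new = t_new[t_new <= stream.t[-1] + 1e-12]
    return AccelStream(
        rate=target_rate,
        t=t_new,
        ax=np.interp(t_new, stream.t, stream.ax),
        ay=np.interp(t_new, stream.t, stream.ay),
        az=np.interp(t_new, stream.t, stream.az),
    )


def _majority_label(window_labels: np.ndarray) -> str:
    """Majority per-sample label; ties go to the window's first sample."""
    counts = Counter(window_labels.tolist())
    top = max(counts.values())
    winners = {lab for lab, c in counts.items() if c == top}
    if len(winners) > 1:
        return window_labels[0]
    return next(iter(winners))


def slice_windows(
    stream: AccelStream,
    width: int = DEFAULT_WIDTH,
    overlap: float = DEFAULT_OVERLAP,
    labels: np.ndarray | None = None,
    subject_id: str | None = None,
) -> list[WindowSlice]:
    """Cut a stream into overlapping fixed-width windows.

    Windows are half-open ``[start, start+width)`` with hop
    ``round(width*(1-overlap))``; the count is ``floor((N-width)/hop) + 1``.
    A stream shorter than ``width`` yields an empty list (logged, not an
    error).  When per-sample ``labels`` are given each window takes the
    majority label, ties resolved to the first sample's label.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    hop = int(round(width * (1 - overlap)))
    if hop < 1:
        raise ValueError("hop must be >= 1; reduce overlap or widen the window")
    n = len(stream)
    if n < width:
        log.warning("stream of %d samples shorter than window width %d; no windows", n, width)
        return []
    if labels is not None and len(labels) != n:
        raise ValueError("labels length must equal stream length")

    vals = stream.values
    out: list[WindowSlice] = []
    for start in range(0, n - width + 1, hop):
        lab = None
        if labels is not None:
            lab = _majority_label(np.asarray(labels, dtype=object)[start : start + width])
        out.append(
            WindowSlice(
                values=vals[start : start + width],
                start_index=start,
                rate=stream.rate,
                label=lab,
                subject_id=subject_id,
            )
        )
    return out


def gravity_correct(window: WindowSlice) -> WindowSlice:
    """Subtract each axis column's mean, removing the gravity component."""
    vals = window.values - window.values.mean(axis=0, keepdims=True)
    return replace(window, values=vals)


def spectral_features(window: WindowSlice, expected_width: int | None = DEFAULT_WIDTH) -> FeatureSequence:
    """Gravity-correct a window and return its one-sided DFT magnitudes.

    Uses the unnormalized DFT, so Parseval's identity reads
    ``sum(x^2) == sum(|X|^2) / width`` over the two-sided spectrum.  After
    mean removal the DC bin is ~0.
    """
    if expected_width is not None and window.width != expected_width:
        raise ValueError(f"expected window width {expected_width}, got {window.width}")
    corrected = gravity_correct(window)
    spec = np.abs(np.fft.rfft(corrected.values, axis=0))
    return FeatureSequence(
        spectra=spec,
        bin_hz=window.rate / window.width,
        label=window.label,
        subject_id=window.subject_id,
        start_index=window.start_index,
    )


def stream_to_features(
    stream: AccelStream,
    labels: np.ndarray | None = None,
    subject_id: str | None = None,
    width: int = DEFAULT_WIDTH,
    overlap: float = DEFAULT_OVERLAP,
    target_rate: float = DEFAULT_RATE,
) -> list[FeatureSequence]:
    """Full preprocessing pipeline: resample -> slice -> correct -> spectra.

    When the stream is resampled, per-sample labels are carried onto the new
    grid by nearest-neighbour lookup before windowing.
    """
    if stream.rate != target_rate:
        resampled = resample(stream, target_rate)
        if labels is not None:
            idx = np.clip(
                np.round((resampled.t - stream.t[0]) * stream.rate).astype(int),
                0,
                len(stream) - 1,
            )
            labels = np.asarray(labels, dtype=object)[idx]
        stream = resampled
    windows = slice_windows(stream, width=width, overlap=overlap, labels=labels, subject_id=subject_id)
    return [spectral_features(w, expected_width=width) for w in windows]


_AXES = ("x", "y", "z")


def features_to_table(features: list[FeatureSequence]):
    """Flatten feature sequences into a DataFrame (one row per window).

    Columns: subject, start_index, label, bin_hz, then one magnitude column
    per (axis, bin) named like ``x_b00``.
    """
    import pandas as pd

    rows = []
    for f in features:
        row = {
            "subject": f.subject_id,
            "start_index": f.start_index,
            "label": f.label,
            "bin_hz": f.bin_hz,
        }
        for a, axis in enumerate(_AXES):
            for b in range(f.spectra.shape[0]):
                row[f"{axis}_b{b:02d}"] = f.spectra[b, a]
        rows.append(row)
    return pd.DataFrame(rows)


def table_to_features(table) -> list[FeatureSequence]:
    """Inverse of :func:`features_to_table`."""
    mag_cols = [c for c in table.columns if len(c) > 2 and c[1:3] == "_b"]
    n_bins = len(mag_cols) // len(_AXES)
    out = []
    for _, row in table.iterrows():
        spec = np.empty((n_bins, 3))
        for a, axis in enumerate(_AXES):
            for b in range(n_bins):
                spec[b, a] = row[f"{axis}_b{b:02d}"]
        label = row.get("label")
        if label is not None and (not isinstance(label, str)) and np.isnan(label):
            label = None
        out.append(
            FeatureSequence(
                spectra=spec,
                bin_hz=float(row.get("bin_hz", 0.5)),
                label=label,
                subject_id=row.get("subject"),
                start_index=int(row.get("start_index", 0)),
            )
        )
    return out
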