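"""Apply a trained classifier to long unlabeled recordings.

Turns a 30-45 min accelerometer stream into per-category window counts (how
often each chest movement was detected), the summary used to profile a
subject's seated activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classifier import TrainedClassifier, predict
from .preprocess import DEFAULT_OVERLAP, DEFAULT_RATE, DEFAULT_WIDTH, stream_to_features
from .signal_synth import ACTIVITY_LABELS, AccelStream

log = logging.getLogger(__name__)

__all__ = ["ActivityCounts", "label_stream"]


@dataclass
class ActivityCounts:
    """Per-class window counts over one recording."""

    counts: dict[str, int]
    total: int
    duration: float  # seconds

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError("per-class counts must sum to total")


def majority_smooth(labels: list[str], k: int = 5) -> list[str]:
    """Sliding majority vote over the window-label track (odd k); off by default."""
    if k % 2 == 0 or k < 1:
        raise ValueError("smoothing window must be a positive odd integer")
    if k == 1 or len(labels) <= 1:
        return list(labels)
    half = k // 2
    out = []
    for i in range(len(labels)):
        seg = labels[max(0, i - half) : i + half + 1]
        vals, cnt = np.unique(seg, return_counts=True)
        winners = vals[cnt == cnt.max()]
        out.append(labels[i] if len(winners) > 1 else str(winners[0]))
    return out


def label_stream(
    model: TrainedClassifier,
    stream: AccelStream,
    width: int = DEFAULT_WIDTH,
    overlap: float = DEFAULT_OVERLAP,
    target_rate: float = DEFAULT_RATE,
    smooth_k: int | None = None,
) -> tuple[ActivityCounts, list[str]]:
    """Classify every window of a recording and tally the categories.

    Runs resample -> slice -> gravity-correct -> spectra -> predict.  Returns
    the per-class counts plus the per-window label track (aligned to window
    start times).  A stream too short for a single window yields zero counts
    with a warning rather than an error.  ``smooth_k`` turns on an optional
    majority-vote smoother over the label track; raw counts are the default.
    """
    duration = len(stream) / stream.rate
    features = stream_to_features(stream, width=width, overlap=overlap, target_rate=target_rate)
    if not features:
        log.warning("recording too short for any window; returning empty counts")
        return ActivityCounts(counts={c: 0 for c in model.classes}, total=0, duration=duration), []
    labels, _ = predict(model, features)
    if smooth_k is not None:
        labels = majority_smooth(labels, smooth_k)
    counts = {c: 0 for c in model.classes}
    for lab in labels:
        counts[lab] += 1
    return ActivityCounts(counts=counts, total=len(labels), duration=duration), labels
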