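"""Synthetic triaxial accelerometer streams for six seated chest movements.

The simulator stands in for chest-worn smartphone recordings: the device sits
flat at the center of the clavicle, so the z axis carries gravity while the
subject is upright, x is lateral (side-to-side sway) and y is
anterior-posterior (back-and-forth rocking).  Each activity class has a simple
kinematic signature -- a sinusoid on its designated axis or a train of
transient pulses -- plus white sensor noise.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ACTIVITY_LABELS",
    "GRAVITY",
    "AccelStream",
    "MotionModelParams",
    "LabeledStream",
    "default_params",
    "simulate_activity",
    "simulate_training_session",
    "write_sensor_log",
    "read_sensor_log",
]

#: Canonical six-class ordering used by every matrix and output table.
ACTIVITY_LABELS: tuple[str, ...] = (
    "walk",
    "stand_sit",
    "rotate",
    "swing",
    "rock",
    "still",
)

GRAVITY = 9.81  # m/s^2

#: Default activity script: each movement held for 10 s, in canonical order.
DEFAULT_SCRIPT: tuple[tuple[str, float], ...] = tuple(
    (label, 10.0) for label in ACTIVITY_LABELS
)


@dataclass
class AccelStream:
    """Uniformly sampled triaxial acceleration record.

    Attributes
    ----------
    rate : float
        Sampling frequency in Hz.
    t : ndarray
        Timestamps in seconds, strictly increasing with spacing ``1/rate``.
    ax, ay, az : ndarray
        Acceleration (m/s^2) in the device frame; z is the gravity axis when
        the phone is worn flat on the clavicle of an upright sitter.
    """

    rate: float
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        n = len(self.t)
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise ValueError("timestamp and axis arrays must have equal length")
        if n == 0:
            raise ValueError("stream must contain at least one sample")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def values(self) -> np.ndarray:
        """(n, 3) array of [x, y, z] samples."""
        return np.column_stack([self.ax, self.ay, self.az])

    @property
    def duration(self) -> float:
        return len(self) / self.rate


@dataclass
class MotionModelParams:
    """Kinematic parameters of one activity's signal model.

    ``freq`` is the dominant oscillation frequency (Hz) and ``amp`` the
    per-axis amplitude triple (m/s^2).  ``pulse_height``/``pulse_width`` shape
    the vertical transient used for stand-up/sit-down events (one pulse every
    ``1/freq`` seconds).
    """

    freq: float = 0.0
    amp: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.3
    gravity: float = GRAVITY
    pulse_height: float = 0.0
    pulse_width: float = 0.5  # seconds

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(a < 0 for a in self.amp):
            raise ValueError("amplitudes must be >= 0")


def default_params(noise_sd: float = 0.3, gravity: float = GRAVITY) -> dict[str, MotionModelParams]:
    """Default per-class motion models.

    Frequencies sit well below the 5 Hz Nyquist limit of a 10 Hz recording and
    match the 2-5 s time span typical of everyday movements: walking bounces
    vertically at a 2 Hz step rate with lateral sway, rotation and swaying are
    slow (0.5-0.6 Hz) horizontal oscillations, and stand/sit events are
    vertical pulses every 2.5 s.
    """
    return {
        "walk": MotionModelParams(freq=2.0, amp=(1.0, 0.5, 3.0), noise_sd=noise_sd, gravity=gravity),
        "stand_sit": MotionModelParams(freq=0.4, amp=(0.0, 0.0, 0.0), noise_sd=noise_sd,
                                       gravity=gravity, pulse_height=4.0, pulse_width=0.5),
        "rotate": MotionModelParams(freq=0.5, amp=(1.5, 1.5, 0.0), noise_sd=noise_sd, gravity=gravity),
        "swing": MotionModelParams(freq=0.6, amp=(2.0, 0.0, 0.0), noise_sd=noise_sd, gravity=gravity),
        "rock": MotionModelParams(freq=0.6, amp=(0.0, 2.0, 0.0), noise_sd=noise_sd, gravity=gravity),
        "still": MotionModelParams(freq=0.0, amp=(0.0, 0.0, 0.0), noise_sd=noise_sd, gravity=gravity),
    }


@dataclass
class LabeledStream:
    """An accelerometer stream with a per-sample activity label track."""

    stream: AccelStream
    labels: np.ndarray
    subject_id: str = "anon"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != len(self.stream):
            raise ValueError("labels length must equal sample count")


def _check_nyquist(label: str, params: MotionModelParams, rate: float) -> None:
    if params.freq >= rate / 2 and params.amp != (0.0, 0.0, 0.0):
        raise ValueError(
            f"{label}: oscillation frequency {params.freq} Hz is at or above "
            f"the Nyquist limit {rate / 2} Hz"
        )
    if params.pulse_height and params.freq >= rate / 2:
        raise ValueError(f"{label}: pulse rate {params.freq} Hz is at or above Nyquist")


def simulate_activity(
    label: str,
    duration: float,
    rate: float = 10.0,
    params: MotionModelParams | None = None,
    seed: int = 0,
) -> AccelStream:
    """Simulate one activity bout as a triaxial acceleration stream.

    Class structure (noise-free): *still* is gravity only; *swing* a lateral
    (x) sinusoid; *rock* an anterior-posterior (y) sinusoid; *rotate*
    quadrature oscillation on both horizontal axes; *walk* a vertical bounce
    at step frequency plus horizontal sway at half the step rate; *stand_sit*
    repeated smooth vertical pulses on top of gravity.

    Parameters default to :func:`default_params` for the class.  Identical
    ``(label, duration, rate, params, seed)`` give an identical stream.
    """
    if label not in ACTIVITY_LABELS:
        raise ValueError(f"unknown activity label {label!r}; expected one of {ACTIVITY_LABELS}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    if params is None:
        params = default_params()[label]
    _check_nyquist(label, params, rate)

    n = int(round(duration * rate))
    t = np.arange(n) / rate
    rng = np.random.default_rng(seed)

    ax = np.zeros(n)
    ay = np.zeros(n)
    az = np.full(n, params.gravity)
    w = 2 * np.pi * params.freq

    if label == "swing":
        ax += params.amp[0] * np.sin(w * t)
    elif label == "rock":
        ay += params.amp[1] * np.sin(w * t)
    elif label == "rotate":
        # quadrature: torso rotation swings the two horizontal axes 90deg apart
        ax += params.amp[0] * np.sin(w * t)
        ay += params.amp[1] * np.cos(w * t)
    elif label == "walk":
        az += params.amp[2] * np.sin(w * t)
        ax += params.amp[0] * np.sin(w * t / 2)
        ay += params.amp[1] * np.sin(w * t / 2 + np.pi / 4)
    elif label == "stand_sit":
        # smooth Gaussian pulses: one stand-up or sit-down every 1/freq seconds
        period = 1.0 / params.freq if params.freq > 0 else duration
        centers = np.arange(period / 2, duration, period)
        sigma = params.pulse_width / 2.355  # FWHM -> sd
        sign = 1.0
        for c in centers:
            az += sign * params.pulse_height * np.exp(-0.5 * ((t - c) / sigma) ** 2)
            sign = -sign  # alternate stand-up / sit-down
    # "still": gravity + noise only

    if params.noise_sd > 0:
        noise = rng.normal(0.0, params.noise_sd, size=(n, 3))
        ax = ax + noise[:, 0]
        ay = ay + noise[:, 1]
        az = az + noise[:, 2]

    return AccelStream(rate=rate, t=t, ax=ax, ay=ay, az=az)


def _jitter_params(
    params: MotionModelParams, rng: np.random.Generator,
    amp_cv: float, freq_cv: float, rate: float,
) -> MotionModelParams:
    """Multiplicative per-subject jitter on amplitudes and frequency."""
    fa = float(np.exp(rng.normal(0.0, amp_cv)))
    ff = float(np.exp(rng.normal(0.0, freq_cv)))
    freq = params.freq * ff
    if freq >= rate / 2:  # keep jittered oscillations physical
        freq = 0.99 * rate / 2
    return replace(
        params,
        freq=freq,
        amp=tuple(a * fa for a in params.amp),
        pulse_height=params.pulse_height * fa,
    )


def simulate_training_session(
    subject_id: str = "A",
    script: tuple[tuple[str, float], ...] = DEFAULT_SCRIPT,
    params: dict[str, MotionModelParams] | None = None,
    seed: int = 0,
    rate: float = 10.0,
    subject_jitter: bool = True,
    amp_cv: float = 0.15,
    freq_cv: float = 0.08,
) -> LabeledStream:
    """Simulate an instructed recording session for one subject.

    The instructor's script is an ordered list of ``(label, duration)`` pairs;
    the default runs the six canonical activities for 10 s each.  With
    ``subject_jitter`` enabled, per-class amplitudes and frequencies get a
    multiplicative log-normal perturbation drawn from a subject-level stream
    seeded by ``(seed, subject_id)``, so distinct subjects move distinctly and
    held-out-subject evaluation is a genuine generalization test.
    """
    if not script:
        raise ValueError("activity script must be non-empty")
    if params is None:
        params = default_params()

    ss = np.random.SeedSequence([seed, zlib.crc32(str(subject_id).encode())])
    subj_rng = np.random.default_rng(ss)
    bout_seeds = subj_rng.integers(0, 2**31, size=len(script))

    streams: list[AccelStream] = []
    labels: list[np.ndarray] = []
    for (label, dur), bseed in zip(script, bout_seeds):
        p = params[label]
        if subject_jitter:
            p = _jitter_params(p, subj_rng, amp_cv, freq_cv, rate)
        s = simulate_activity(label, dur, rate=rate, params=p, seed=int(bseed))
        streams.append(s)
        labels.append(np.full(len(s), label, dtype=object))

    vals = np.concatenate([s.values for s in streams])
    n = len(vals)
    t = np.arange(n) / rate
    stream = AccelStream(rate=rate, t=t, ax=vals[:, 0], ay=vals[:, 1], az=vals[:, 2])
    return LabeledStream(stream=stream, labels=np.concatenate(labels), subject_id=subject_id)


class SensorLogError(ValueError):
    """Raised when a sensor-log CSV is malformed."""


def write_sensor_log(stream: AccelStream, path) -> None:
    """Write a stream as a ``Timestamp,X,Y,Z`` CSV (seconds from stream start)."""
    with open(path, "w", newline="") as fh:
        fh.write("Timestamp,X,Y,Z\n")
        for ti, x, y, z in zip(stream.t, stream.ax, stream.ay, stream.az):
            fh.write(f"{ti:.6f},{x:.6f},{y:.6f},{z:.6f}\n")


def read_sensor_log(path, rate: float | None = None) -> AccelStream:
    """Read a ``Timestamp,X,Y,Z`` sensor log.

    The sampling rate is inferred from the median timestamp spacing unless
    given.  Malformed rows, missing columns, an empty file or non-monotone
    timestamps raise :class:`SensorLogError` naming the offending line.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    if not lines:
        raise SensorLogError(f"{path}: empty sensor log")
    header = [c.strip() for c in lines[0].split(",")]
    if header != ["Timestamp", "X", "Y", "Z"]:
        raise SensorLogError(f"{path}: line 1: expected header Timestamp,X,Y,Z, got {lines[0]!r}")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise SensorLogError(f"{path}: line {lineno}: expected 4 columns, got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise SensorLogError(f"{path}: line {lineno}: {exc}") from None
    if not rows:
        raise SensorLogError(f"{path}: sensor log contains no data rows")
    arr = np.asarray(rows)
    t = arr[:, 0]
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        bad = int(np.nonzero(np.diff(t) <= 0)[0][0]) + 3  # +2 header/0-base, +1 second row
        raise SensorLogError(f"{path}: line {bad}: timestamps not strictly increasing")
    if rate is None:
        # median spacing, rounded so decimal timestamps give an exact rate
        rate = round(1.0 / float(np.median(np.diff(t))), 6) if len(t) > 1 else 10.0
    return AccelStream(rate=rate, t=t, ax=arr[:, 1], ay=arr[:, 2], az=arr[:, 3])
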