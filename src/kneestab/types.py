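"""Core data containers shared across the pipeline.

Conventions
-----------
* Internal units are SI: m/s² for acceleration, rad/s for angular velocity,
  µT for the magnetic field, N for force, seconds for time.  The reporting
  layer converts angular rates to °/s to match clinical tables.
* The sensor x-axis is aligned with the longitudinal axis of the instrumented
  segment; y is (approximately) medio-lateral, z antero-posterior.
* Sample-index windows are half-open ``[start, stop)`` unless noted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InvalidConfigError

G = 9.80665  # standard gravity, m/s²

#: full-range scales of the sensor class this pipeline targets
ACC_RANGE = 16 * G                 # ±16 g, m/s²
GYRO_RANGE = np.deg2rad(2000.0)    # ±2000 °/s, rad/s
MAG_RANGE = 4800.0                 # ±4800 µT


@dataclass
class ImuRecording:
    """Tri-axial accelerometer/gyroscope/magnetometer streams of one sensor.

    Attributes
    ----------
    t : (N,) array of sample times in seconds, strictly increasing.
    acc : (N, 3) linear acceleration (specific force), m/s².
    gyro : (N, 3) angular velocity, rad/s.
    mag : (N, 3) magnetic field, µT.
    fs : sampling rate, Hz.
    location : ``"foot"`` or ``"tibia"``.
    y_flipped : declared inverted mounting of the sensor y-axis.
    """

    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray
    fs: float
    location: str
    y_flipped: bool = False

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.mag = np.asarray(self.mag, dtype=float)
        n = len(self.t)
        for name in ("acc", "gyro", "mag"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise InvalidConfigError(
                    f"{name} has shape {arr.shape}, expected ({n}, 3)")
        if self.fs <= 0:
            raise InvalidConfigError(f"fs must be > 0, got {self.fs}")
        if self.location not in ("foot", "tibia"):
            raise InvalidConfigError(
                f"location must be 'foot' or 'tibia', got {self.location!r}")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise InvalidConfigError("time vector is not strictly increasing")
        if np.any(np.abs(self.acc) > ACC_RANGE * 1.001):
            raise InvalidConfigError("acceleration exceeds the ±16 g range")
        if np.any(np.abs(self.gyro) > GYRO_RANGE * 1.001):
            raise InvalidConfigError("angular velocity exceeds ±2000 °/s")

    def __len__(self):
        return len(self.t)

    def __eq__(self, other):
        if not isinstance(other, ImuRecording):
            return NotImplemented
        return (
            self.fs == other.fs
            and self.location == other.location
            and self.y_flipped == other.y_flipped
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.acc, other.acc)
            and np.array_equal(self.gyro, other.gyro)
            and np.array_equal(self.mag, other.mag)
        )


@dataclass
class GrfRecording:
    """Vertical ground-reaction-force stream from one force plate."""

    t: np.ndarray
    grfv: np.ndarray
    fs: float
    body_mass: float

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.grfv = np.asarray(self.grfv, dtype=float)
        if self.grfv.shape != self.t.shape:
            raise InvalidConfigError("t and grfv must have the same length")
        if self.fs <= 0 or self.body_mass <= 0:
            raise InvalidConfigError("fs and body_mass must be > 0")
        if np.any(self.grfv < 0):
            raise InvalidConfigError("grfv must be non-negative")

    def __len__(self):
        return len(self.t)


@dataclass
class OrientationSeries:
    """Per-sample orientation estimate from the complementary filter.

    ``rotations`` maps sensor-frame vectors to a vertically aligned inertial
    frame (z up); ``pitch_y`` is the rotation about the sensor y-axis
    relative to the initial still posture, in degrees, positive for knee
    flexion (tibia inclining forward).
    """

    t: np.ndarray
    pitch_y: np.ndarray          # degrees
    global_acc: np.ndarray       # (N, 3), m/s², vertically aligned frame
    rotations: np.ndarray        # (N, 3, 3), sensor->global
    fs: float
    location: str
    k1: float
    k2: float


@dataclass
class TaskEvents:
    """Detected (or ground-truth) event indices for one trial.

    SLS: ``i_start``, ``i_epe``, ``i_end``.
    CHT: ``to`` / ``la`` (sample indices of take-offs / landings) and
    ``risk_windows`` — half-open ``(start, stop)`` ranges of length
    ``round(0.1·fs)`` following each landing.
    CMJ: ``i_unweight_end``, ``i_flight_start``.
    """

    task: str
    fs: float
    i_start: Optional[int] = None
    i_epe: Optional[int] = None
    i_end: Optional[int] = None
    to: list = field(default_factory=list)
    la: list = field(default_factory=list)
    risk_windows: list = field(default_factory=list)
    i_unweight_end: Optional[int] = None
    i_flight_start: Optional[int] = None

    def to_dict(self):
        """JSON-serializable form with indices and seconds."""
        def sec(i):
            return None if i is None else i / self.fs
        return {
            "task": self.task,
            "fs": self.fs,
            "i_start": self.i_start, "t_start": sec(self.i_start),
            "i_epe": self.i_epe, "t_epe": sec(self.i_epe),
            "i_end": self.i_end, "t_end": sec(self.i_end),
            "to": list(map(int, self.to)),
            "la": list(map(int, self.la)),
            "to_s": [i / self.fs for i in self.to],
            "la_s": [i / self.fs for i in self.la],
            "risk_windows": [[int(a), int(b)] for a, b in self.risk_windows],
            "i_unweight_end": self.i_unweight_end,
            "t_unweight_end": sec(self.i_unweight_end),
            "i_flight_start": self.i_flight_start,
            "t_flight_start": sec(self.i_flight_start),
        }


@dataclass
class GroundTruth:
    """Simulator bookkeeping: true event times, parameter values, variance."""

    event_times: dict = field(default_factory=dict)   # name -> seconds
    true_parameter_values: dict = field(default_factory=dict)
    true_icc: Optional[float] = None

    def __post_init__(self):
        if self.true_icc is not None and not 0.0 <= self.true_icc <= 1.0:
            raise InvalidConfigError("true_icc must lie in [0, 1]")


@dataclass
class FeatureRecord:
    """One trial's extracted parameter set."""

    subject: str
    limb: str                    # "dominant" | "non-dominant"
    task: str                    # "SLS" | "CHT" | "CMJ"
    trial: int
    values: dict = field(default_factory=dict)

    def as_rows(self):
        """Tidy rows: one dict per parameter."""
        return [
            {"subject": self.subject, "limb": self.limb, "task": self.task,
             "trial": self.trial, "parameter": k, "value": v}
            for k, v in self.values.items()
        ]
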