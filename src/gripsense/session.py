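"""Core session data model.

A *session set* is the basic unit of the study design: one participant, on
one day, performs two dynamometer squeezes (averaged into the ground-truth
grip value) followed by one execution each of the tap, flick and drag
tasks.  Touch samples and 60 Hz inertial frames are stored as column
arrays for efficiency; single-sample views are available through
``TouchStream.sample`` / ``InertialStream.frame``.

Conventions: coordinates are millimeters with the origin at the screen's
top-left corner and y increasing downward; timestamps are seconds as
float64, zeroed at task start; contact area stays in the device's
normalized (dimensionless) units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from gripsense.errors import ValidationError

TASKS = ("tap", "flick", "drag")

#: phase codes for touch samples
PHASES = ("down", "move", "up")

#: sensor channel names, fixed ordering used throughout the feature layer
SENSOR_CHANNELS = (
    "acc_x", "acc_y", "acc_z",
    "gyr_x", "gyr_y", "gyr_z",
    "ori_x", "ori_y", "ori_z",
)


@dataclass(frozen=True)
class ScreenSpec:
    """Physical screen footprint in mm (default: Google Pixel 7a)."""

    width_mm: float = 72.9
    height_mm: float = 152.0


@dataclass(frozen=True)
class GripMeasurement:
    """Two consecutive dynamometer readings for one set, in kg.

    The ground truth is always derived as the arithmetic mean of the two
    readings and never stored redundantly.
    """

    reading_1: float
    reading_2: float

    def __post_init__(self) -> None:
        for name in ("reading_1", "reading_2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"grip {name} must be finite and >= 0, got {v!r}")

    @property
    def ground_truth(self) -> float:
        """Mean of the two readings, in kg."""
        return 0.5 * (self.reading_1 + self.reading_2)


@dataclass(frozen=True)
class TouchSample:
    t: float
    x: float
    y: float
    phase: str
    contact_area: float


@dataclass
class TouchStream:
    """Columnar touch-event stream: time (s), position (mm), phase, area."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    phase: np.ndarray  # array of str, each in PHASES
    contact_area: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.phase = np.asarray(self.phase, dtype="U4")
        self.contact_area = np.asarray(self.contact_area, dtype=float)

    def __len__(self) -> int:
        return self.t.size

    def sample(self, i: int) -> TouchSample:
        return TouchSample(
            float(self.t[i]), float(self.x[i]), float(self.y[i]),
            str(self.phase[i]), float(self.contact_area[i]),
        )

    def validate(self, screen: ScreenSpec | None = None) -> None:
        n = len(self)
        arrays = (self.t, self.x, self.y, self.phase, self.contact_area)
        if any(a.shape != (n,) for a in arrays):
            raise ValidationError("touch stream columns have inconsistent lengths")
        if n == 0:
            return
        if np.any(self.t < 0) or not np.all(np.isfinite(self.t)):
            raise ValidationError("touch timestamps must be finite and non-negative")
        if np.any(np.diff(self.t) < 0):
            raise ValidationError("touch samples must be sorted by time")
        if np.any(self.contact_area < 0):
            raise ValidationError("contact area must be >= 0")
        bad = set(np.unique(self.phase)) - set(PHASES)
        if bad:
            raise ValidationError(f"unknown touch phases: {sorted(bad)}")
        if screen is not None:
            if np.any(self.x < 0) or np.any(self.x > screen.width_mm):
                raise ValidationError("touch x outside screen bounds")
            if np.any(self.y < 0) or np.any(self.y > screen.height_mm):
                raise ValidationError("touch y outside screen bounds")

    def copy(self) -> "TouchStream":
        return TouchStream(self.t.copy(), self.x.copy(), self.y.copy(),
                           self.phase.copy(), self.contact_area.copy())


@dataclass(frozen=True)
class InertialFrame:
    t: float
    accel: np.ndarray
    gyro: np.ndarray
    orientation: np.ndarray


@dataclass
class InertialStream:
    """Columnar inertial stream at a nominal 60 Hz.

    ``accel`` (m/s^2), ``gyro`` (rad/s) and ``orientation`` (degrees of
    device attitude) are (n, 3) arrays; missing values are NaN until
    interpolation, after which none may remain.
    """

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    orientation: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float).reshape(-1, 3)
        self.gyro = np.asarray(self.gyro, dtype=float).reshape(-1, 3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return self.t.size

    def frame(self, i: int) -> InertialFrame:
        return InertialFrame(float(self.t[i]), self.accel[i].copy(),
                             self.gyro[i].copy(), self.orientation[i].copy())

    def matrix(self) -> np.ndarray:
        """(n, 9) channel matrix ordered as SENSOR_CHANNELS."""
        return np.hstack([self.accel, self.gyro, self.orientation])

    @classmethod
    def from_matrix(cls, t: np.ndarray, m: np.ndarray) -> "InertialStream":
        m = np.asarray(m, dtype=float)
        return cls(t, m[:, 0:3], m[:, 3:6], m[:, 6:9])

    def validate(self, allow_missing: bool = True) -> None:
        n = len(self)
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3) \
                or self.orientation.shape != (n, 3):
            raise ValidationError("inertial stream columns have inconsistent shapes")
        if n == 0:
            return
        if not np.all(np.isfinite(self.t)):
            raise ValidationError("inertial timestamps must be finite")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError("inertial frames must be strictly increasing in time")
        if not allow_missing and not np.all(np.isfinite(self.matrix())):
            raise ValidationError("inertial stream contains missing values")

    def copy(self) -> "InertialStream":
        return InertialStream(self.t.copy(), self.accel.copy(),
                              self.gyro.copy(), self.orientation.copy())


@dataclass(frozen=True)
class SubEvent:
    """One target interaction inside a task execution.

    ``t_input`` is the event time used for anchoring the sensor windows;
    for taps it is the moment the target was hit, for flicks the stroke
    release, for the drag the trace midpoint.
    """

    index: int
    t_appear: float
    t_input: float
    target_x: float
    target_y: float
    success: bool = True

    def __post_init__(self) -> None:
        if self.t_input < self.t_appear:
            raise ValidationError(
                f"sub-event {self.index}: t_input ({self.t_input}) precedes "
                f"t_appear ({self.t_appear})")


# number of sub-events each task must contain
SUBEVENTS_PER_TASK = {"tap": 10, "flick": 10, "drag": 1}


@dataclass
class TaskExecution:
    """One run of a tap, flick or drag task."""

    task: str
    sub_events: list[SubEvent]
    touch: TouchStream
    sensor: InertialStream
    elapsed: float
    spiral: "object | None" = None  # SpiralSpec for drag executions

    def validate(self, screen: ScreenSpec | None = None,
                 allow_missing: bool = True) -> None:
        if self.task not in TASKS:
            raise ValidationError(f"unknown task {self.task!r}")
        expected = SUBEVENTS_PER_TASK[self.task]
        if len(self.sub_events) != expected:
            raise ValidationError(
                f"{self.task} execution must contain exactly {expected} "
                f"sub-events, got {len(self.sub_events)}")
        if not self.elapsed > 0:
            raise ValidationError("elapsed must be positive")
        self.touch.validate(screen)
        self.sensor.validate(allow_missing=allow_missing)
        if self.task == "drag" and self.spiral is None:
            raise ValidationError("drag execution requires a spiral spec")

    def copy(self) -> "TaskExecution":
        return TaskExecution(self.task, list(self.sub_events), self.touch.copy(),
                             self.sensor.copy(), self.elapsed, self.spiral)


@dataclass
class SessionSet:
    """One participant-day-set unit: grip ground truth plus three executions."""

    participant_id: str
    day: int
    set_index: int
    grip: GripMeasurement
    executions: Mapping[str, TaskExecution]
    hand: str = "right"
    handedness: str = "dominant"

    def validate(self, screen: ScreenSpec | None = None,
                 allow_missing: bool = True) -> None:
        where = f"participant={self.participant_id} day={self.day} set={self.set_index}"
        if self.day < 1:
            raise ValidationError(f"{where}: day must be >= 1")
        if not 1 <= self.set_index <= 10:
            raise ValidationError(f"{where}: set_index must be in 1..10")
        if self.hand not in ("left", "right"):
            raise ValidationError(f"{where}: hand must be left or right")
        if self.handedness not in ("dominant", "nondominant"):
            raise ValidationError(f"{where}: handedness must be dominant/nondominant")
        if set(self.executions) != set(TASKS):
            raise ValidationError(
                f"{where}: expected one execution per task {TASKS}, "
                f"got {sorted(self.executions)}")
        for task, ex in self.executions.items():
            if ex.task != task:
                raise ValidationError(f"{where}: execution under key {task!r} "
                                      f"has task {ex.task!r}")
            try:
                ex.validate(screen, allow_missing=allow_missing)
            except ValidationError as e:
                raise ValidationError(f"{where}: {e}") from e

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.participant_id, self.day, self.set_index)


def sort_sessions(sessions: Iterable[SessionSet]) -> list[SessionSet]:
    """Canonical ordering: (participant_id, day, set_index)."""
    return sorted(sessions, key=lambda s: s.key)
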