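"""Behavioral and windowed-sensor feature extraction.

Each task execution becomes one feature row (the study design maps one
grip measurement to one execution).  Per-sub-event quantities — spatial
error, elimination time, touch duration, contact area, flick direction —
are aggregated across the 10 sub-events by their mean (standard
deviations can additionally be emitted); the drag task contributes
tracing accuracy and touch-path kinematics.  Every anchor also yields 99
windowed sensor statistics: for each of the 9 channels and each of the
pre / post windows, the max, min, range, mean and mean absolute
consecutive-frame difference, plus the 9 during-input channel values.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from gripsense.errors import DataError, UsageError
from gripsense.geometry import SpiralSpec, distance_to_spiral
from gripsense.preprocessing import EventWindows, extract_windows, preprocess_stream
from gripsense.session import SENSOR_CHANNELS, SessionSet, TaskExecution, TouchStream

#: columns that key a feature row back to its session set
KEY_COLUMNS = ("participant_id", "day", "set_index")
TARGET_COLUMN = "grip_kg"

_WINDOW_STATS = ("max", "min", "range", "mean", "absdiff_mean")


@dataclass
class FeatureVector:
    """Named feature values for one task execution (or their unified concatenation)."""

    names: tuple[str, ...]
    values: np.ndarray
    task_scope: str  # tap | flick | drag | unified
    grip_kg: float = np.nan
    participant_id: str = ""
    day: int = 0
    set_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise UsageError("feature names and values differ in length")
        if len(set(self.names)) != len(self.names):
            raise UsageError("feature names must be unique")

    def validate(self) -> None:
        if not np.all(np.isfinite(self.values)):
            bad = [n for n, v in zip(self.names, self.values) if not np.isfinite(v)]
            raise DataError(f"non-finite feature values: {bad}")

    @property
    def schema_hash(self) -> str:
        return schema_hash(self.names)


def schema_hash(names: Sequence[str]) -> str:
    """Stable 12-hex-digit digest of an ordered feature-name list."""
    h = hashlib.sha1("\x1f".join(names).encode()).hexdigest()
    return h[:12]


def sensor_stats(windows: EventWindows) -> dict[str, float]:
    """The 99 windowed sensor statistics for one anchor.

    9 channels x {pre, post} x {max, min, range, mean, absdiff_mean}
    plus the 9 during-input channel averages.
    """
    out: dict[str, float] = {}
    for win_name, rows in (("pre", windows.pre), ("post", windows.post)):
        mx = rows.max(axis=0)
        mn = rows.min(axis=0)
        mean = rows.mean(axis=0)
        dmean = np.abs(np.diff(rows, axis=0)).mean(axis=0)
        for c, ch in enumerate(SENSOR_CHANNELS):
            out[f"{win_name}_{ch}_max"] = float(mx[c])
            out[f"{win_name}_{ch}_min"] = float(mn[c])
            out[f"{win_name}_{ch}_range"] = float(mx[c] - mn[c])
            out[f"{win_name}_{ch}_mean"] = float(mean[c])
            out[f"{win_name}_{ch}_absdiff_mean"] = float(dmean[c])
    for c, ch in enumerate(SENSOR_CHANNELS):
        out[f"during_{ch}"] = float(windows.during[c])
    return out


def _mean_sensor_stats(windows_list: Sequence[EventWindows]) -> dict[str, float]:
    per_event = [sensor_stats(w) for w in windows_list]
    names = list(per_event[0])
    return {n: float(np.mean([d[n] for d in per_event])) for n in names}


def _strokes(touch: TouchStream) -> list[tuple[int, int]]:
    """(down_index, up_index) pairs delimiting each touch stroke."""
    downs = np.nonzero(touch.phase == "down")[0]
    ups = np.nonzero(touch.phase == "up")[0]
    pairs = []
    for d in downs:
        after = ups[ups >= d]
        if after.size == 0:
            raise DataError("touch-down without a matching touch-up")
        pairs.append((int(d), int(after[0])))
    return pairs


def _match_stroke(strokes: list[tuple[int, int]], touch: TouchStream,
                  t_input: float) -> tuple[int, int]:
    if not strokes:
        raise DataError("no touch strokes in execution")
    downs = np.array([touch.t[d] for d, _ in strokes])
    return strokes[int(np.argmin(np.abs(downs - t_input)))]


def _behavior_block(per_event: dict[str, list[float]], emit_sd: bool
                    ) -> dict[str, float]:
    out: dict[str, float] = {}
    for name, vals in per_event.items():
        out[name] = float(np.mean(vals))
    if emit_sd:
        for name, vals in per_event.items():
            out[f"{name}_sd"] = float(np.std(vals))
    return out


def tap_features(execution: TaskExecution,
                 windows_list: Sequence[EventWindows],
                 emit_sd: bool = False) -> FeatureVector:
    """Tap-task feature row: target accuracy, timing, contact area, sensors.

    Per sub-event: spatial error (mm from the touch-down point to the
    target center), elimination time (t_input - t_appear), touch duration
    (down to up) and mean contact area over the stroke; aggregated by
    mean over the 10 sub-events.
    """
    if execution.task != "tap":
        raise UsageError(f"tap_features got a {execution.task} execution")
    if len(windows_list) != len(execution.sub_events):
        raise UsageError("need one EventWindows per sub-event")
    strokes = _strokes(execution.touch)
    touch = execution.touch
    per = {"spatial_error_mm": [], "elimination_time_s": [],
           "touch_duration_s": [], "contact_area": []}
    for ev in execution.sub_events:
        d, u = _match_stroke(strokes, touch, ev.t_input)
        per["spatial_error_mm"].append(
            float(np.hypot(touch.x[d] - ev.target_x, touch.y[d] - ev.target_y)))
        per["elimination_time_s"].append(ev.t_input - ev.t_appear)
        per["touch_duration_s"].append(float(touch.t[u] - touch.t[d]))
        per["contact_area"].append(float(touch.contact_area[d:u + 1].mean()))
    block = _behavior_block(per, emit_sd)
    block.update(_mean_sensor_stats(windows_list))
    return FeatureVector(tuple(block), np.array(list(block.values())), "tap")


def flick_features(execution: TaskExecution,
                   windows_list: Sequence[EventWindows],
                   emit_sd: bool = False) -> FeatureVector:
    """Flick-task feature row: stroke direction, timing, contact area, sensors.

    The flick direction is the unit vector from the first to the last
    touch sample of the stroke (x, y components in screen coordinates).
    Zero-length strokes have no direction; such sub-events are excluded
    from the behavioral aggregate and counted.
    """
    if execution.task != "flick":
        raise UsageError(f"flick_features got a {execution.task} execution")
    if len(windows_list) != len(execution.sub_events):
        raise UsageError("need one EventWindows per sub-event")
    strokes = _strokes(execution.touch)
    touch = execution.touch
    per = {"direction_x": [], "direction_y": [], "elimination_time_s": [],
           "stroke_duration_s": [], "contact_area": []}
    excluded = 0
    for ev in execution.sub_events:
        d, u = _match_stroke(strokes, touch, ev.t_input)
        dx, dy = touch.x[u] - touch.x[d], touch.y[u] - touch.y[d]
        norm = float(np.hypot(dx, dy))
        if norm == 0.0:
            excluded += 1
            continue
        per["direction_x"].append(dx / norm)
        per["direction_y"].append(dy / norm)
        per["elimination_time_s"].append(ev.t_input - ev.t_appear)
        per["stroke_duration_s"].append(float(touch.t[u] - touch.t[d]))
        per["contact_area"].append(float(touch.contact_area[d:u + 1].mean()))
    if not per["direction_x"]:
        raise DataError("all flick strokes were zero-length")
    block = _behavior_block(per, emit_sd)
    block.update(_mean_sensor_stats(windows_list))
    fv = FeatureVector(tuple(block), np.array(list(block.values())), "flick")
    fv.excluded_sub_events = excluded  # bookkeeping, surfaced in logs
    return fv


def drag_features(execution: TaskExecution, spec: SpiralSpec | None,
                  windows: EventWindows) -> FeatureVector:
    """Drag-task feature row: tracing accuracy, path kinematics, sensors.

    Tracing accuracy is the mean distance from each touch sample to the
    nearest point on the reference spiral centerline.  Velocity and
    acceleration come from finite differences of the raw touch path
    (mm/s, mm/s^2), summarized by mean and max magnitudes.
    """
    if execution.task != "drag":
        raise UsageError(f"drag_features got a {execution.task} execution")
    if spec is None:
        spec = execution.spiral
    if spec is None:
        raise UsageError("drag execution carries no spiral spec")
    touch = execution.touch
    if len(touch) < 3:
        raise DataError("drag needs >= 3 touch samples for acceleration")
    pts = np.column_stack([touch.x, touch.y])
    tracing = float(np.mean(distance_to_spiral(spec, pts)))
    vx = np.gradient(touch.x, touch.t)
    vy = np.gradient(touch.y, touch.t)
    speed = np.hypot(vx, vy)
    ax = np.gradient(vx, touch.t)
    ay = np.gradient(vy, touch.t)
    amag = np.hypot(ax, ay)
    block = {
        "tracing_error_mm": tracing,
        "speed_mean_mm_s": float(speed.mean()),
        "speed_max_mm_s": float(speed.max()),
        "accel_mean_mm_s2": float(amag.mean()),
        "accel_max_mm_s2": float(amag.max()),
        "contact_area": float(touch.contact_area.mean()),
        "duration_s": float(touch.t[-1] - touch.t[0]),
    }
    block.update(sensor_stats(windows))
    return FeatureVector(tuple(block), np.array(list(block.values())), "drag")


def assemble_unified(tap: FeatureVector, flick: FeatureVector,
                     drag: FeatureVector) -> FeatureVector:
    """Concatenate the three task rows into one unified row with prefixed names."""
    parts = {"tap": tap, "flick": flick, "drag": drag}
    keys = {(v.participant_id, v.day, v.set_index) for v in parts.values()}
    if len(keys) != 1:
        raise UsageError(f"mismatched session keys across tasks: {sorted(keys)}")
    grips = {v.grip_kg for v in parts.values()}
    if len(grips) != 1:
        raise UsageError("mismatched grip ground truth across tasks")
    names, values = [], []
    for prefix, fv in parts.items():
        names.extend(f"{prefix}_{n}" for n in fv.names)
        values.append(fv.values)
    ref = tap
    return FeatureVector(tuple(names), np.concatenate(values), "unified",
                         grip_kg=ref.grip_kg, participant_id=ref.participant_id,
                         day=ref.day, set_index=ref.set_index)


def extract_set_features(session: SessionSet, cutoff: float = 20.0,
                         emit_sd: bool = False) -> dict[str, FeatureVector]:
    """Feature vectors for all four scopes of one session set.

    Sensor streams are interpolated and low-pass filtered, windows are
    anchored at each sub-event's input time (the trace midpoint for the
    drag), and the per-task extractors run on the result.
    """
    out: dict[str, FeatureVector] = {}
    meta = dict(grip_kg=session.grip.ground_truth,
                participant_id=session.participant_id,
                day=session.day, set_index=session.set_index)

    padded: dict[str, int] = {}
    for task in ("tap", "flick"):
        ex = session.executions[task]
        stream = preprocess_stream(ex.sensor, cutoff=cutoff)
        wins = [extract_windows(stream, ev.t_input) for ev in ex.sub_events]
        fn = tap_features if task == "tap" else flick_features
        out[task] = replace(fn(ex, wins, emit_sd=emit_sd), **meta)
        padded[task] = sum(w.pre_padded + w.post_padded for w in wins)

    ex = session.executions["drag"]
    stream = preprocess_stream(ex.sensor, cutoff=cutoff)
    anchor = 0.5 * (float(ex.touch.t[0]) + float(ex.touch.t[-1]))
    win = extract_windows(stream, anchor)
    out["drag"] = replace(drag_features(ex, ex.spiral, win), **meta)
    padded["drag"] = win.pre_padded + win.post_padded

    out["unified"] = assemble_unified(out["tap"], out["flick"], out["drag"])
    padded["unified"] = sum(padded.values())
    for scope, fv in out.items():
        fv.n_padded_frames = padded[scope]
        fv.validate()
    return out


def build_feature_tables(sessions: Iterable[SessionSet], cutoff: float = 20.0,
                         emit_sd: bool = False) -> dict[str, pd.DataFrame]:
    """All four scope matrices in one pass over the sessions."""
    rows: dict[str, list] = {s: [] for s in ("tap", "flick", "drag", "unified")}
    names: dict[str, tuple[str, ...]] = {}
    padded: dict[str, int] = {s: 0 for s in rows}
    excluded = 0
    for session in sessions:
        fvs = extract_set_features(session, cutoff=cutoff, emit_sd=emit_sd)
        for scope, fv in fvs.items():
            if scope not in names:
                names[scope] = fv.names
            elif fv.names != names[scope]:
                raise UsageError("inconsistent feature schema across sessions")
            rows[scope].append((fv.participant_id, fv.day, fv.set_index,
                                *fv.values, fv.grip_kg))
            padded[scope] += getattr(fv, "n_padded_frames", 0)
        excluded += getattr(fvs["flick"], "excluded_sub_events", 0)
    if not names:
        raise UsageError("no sessions given")
    out = {}
    for scope, recs in rows.items():
        cols = [*KEY_COLUMNS, *names[scope], TARGET_COLUMN]
        df = pd.DataFrame(recs, columns=cols)
        df.attrs["schema_hash"] = schema_hash(names[scope])
        df.attrs["task_scope"] = scope
        df.attrs["padded_window_frames"] = padded[scope]
        df.attrs["excluded_flick_sub_events"] = excluded
        out[scope] = df
    return out


def build_feature_table(sessions: Iterable[SessionSet], scope: str = "unified",
                        cutoff: float = 20.0, emit_sd: bool = False
                        ) -> pd.DataFrame:
    """Feature matrix for one scope: key columns, features, and grip_kg last."""
    if scope not in ("tap", "flick", "drag", "unified"):
        raise UsageError(f"unknown scope {scope!r}")
    return build_feature_tables(sessions, cutoff=cutoff, emit_sd=emit_sd)[scope]


def feature_columns(df: pd.DataFrame) -> list[str]:
    """The feature columns of a matrix (everything but keys and target)."""
    skip = set(KEY_COLUMNS) | {TARGET_COLUMN}
    return [c for c in df.columns if c not in skip]


_BEHAVIOR_DOC = {
    "spatial_error_mm": ("mm", "touch-down point to target center, mean over sub-events"),
    "elimination_time_s": ("s", "target appearance to input event, mean over sub-events"),
    "touch_duration_s": ("s", "touch-down to touch-up, mean over sub-events"),
    "stroke_duration_s": ("s", "flick stroke start to release, mean over sub-events"),
    "contact_area": ("device units", "mean finger contact area over the stroke"),
    "direction_x": ("unitless", "x component of the stroke-start-to-end unit vector, mean"),
    "direction_y": ("unitless", "y component of the stroke-start-to-end unit vector, mean"),
    "tracing_error_mm": ("mm", "mean distance to nearest spiral centerline point"),
    "speed_mean_mm_s": ("mm/s", "mean touch-path speed (central differences)"),
    "speed_max_mm_s": ("mm/s", "max touch-path speed"),
    "accel_mean_mm_s2": ("mm/s^2", "mean touch-path acceleration magnitude"),
    "accel_max_mm_s2": ("mm/s^2", "max touch-path acceleration magnitude"),
    "duration_s": ("s", "drag touch-down to touch-up"),
}

_SENSOR_UNITS = {"acc": "m/s^2", "gyr": "rad/s", "ori": "deg"}
_STAT_DOC = {
    "max": "window maximum", "min": "window minimum",
    "range": "window max - min", "mean": "window mean",
    "absdiff_mean": "mean absolute consecutive-frame difference",
}


def feature_dictionary(names: Sequence[str]) -> dict[str, dict[str, str]]:
    """Unit and definition for every feature name (for a JSON data dictionary)."""
    out: dict[str, dict[str, str]] = {}
    for name in names:
        base = name
        prefix = ""
        for task in ("tap", "flick", "drag"):
            if name.startswith(f"{task}_"):
                base, prefix = name[len(task) + 1:], f"{task} task: "
                break
        if base in _BEHAVIOR_DOC:
            unit, desc = _BEHAVIOR_DOC[base]
        elif base.endswith("_sd") and base[:-3] in _BEHAVIOR_DOC:
            unit, desc = _BEHAVIOR_DOC[base[:-3]]
            desc = desc.replace("mean over", "SD over")
        else:
            parts = base.split("_")
            if parts[0] == "during":
                unit = _SENSOR_UNITS[parts[1]]
                desc = f"{parts[1]}_{parts[2]} averaged at the input time"
            else:
                win, grp, axis = parts[0], parts[1], parts[2]
                stat = "_".join(parts[3:])
                unit = _SENSOR_UNITS[grp]
                desc = (f"{grp}_{axis} {_STAT_DOC[stat]} over the 10-frame "
                        f"{win}-input window")
        out[name] = {"unit": unit, "definition": prefix + desc}
    return out
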