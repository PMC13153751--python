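"""Session-log, feature-matrix and report readers/writers.

Session logs are JSON Lines: the first line is a header object declaring
the schema version, device string, screen size in mm and nominal sensor
rate; every following line is one session set with columnar stream
arrays.  A ``csv-bundle`` dialect (a directory of four CSV tables) is
also supported for interoperability with spreadsheet tooling.

Coordinates are stored in mm; if a log was captured in pixels the header
declares ``dots_per_mm`` and conversion happens at read time.  Floats are
serialized with 12 significant digits, so write-then-read round-trips to
well within 1e-9 relative tolerance.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from gripsense.errors import SchemaError, UsageError, ValidationError
from gripsense.features import (
    KEY_COLUMNS,
    TARGET_COLUMN,
    FeatureVector,
    feature_columns,
    schema_hash,
)
from gripsense.geometry import SpiralSpec
from gripsense.session import (
    GripMeasurement,
    InertialStream,
    ScreenSpec,
    SessionSet,
    SubEvent,
    TaskExecution,
    TouchStream,
    sort_sessions,
)

SCHEMA_VERSION = "gripsense-session/1"


def _round_floats(obj):
    if isinstance(obj, float):
        return None if math.isnan(obj) else float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def _nan_to_num(values) -> np.ndarray:
    return np.array([np.nan if v is None else v for v in values], dtype=float)


def _execution_to_obj(ex: TaskExecution) -> dict:
    obj = {
        "task": ex.task,
        "elapsed": ex.elapsed,
        "sub_events": [
            {"index": e.index, "t_appear": e.t_appear, "t_input": e.t_input,
             "target_x": e.target_x, "target_y": e.target_y, "success": e.success}
            for e in ex.sub_events
        ],
        "touch": {
            "t": ex.touch.t.tolist(), "x": ex.touch.x.tolist(),
            "y": ex.touch.y.tolist(), "phase": ex.touch.phase.tolist(),
            "area": ex.touch.contact_area.tolist(),
        },
        "sensor": {
            "t": ex.sensor.t.tolist(),
            "accel": ex.sensor.accel.tolist(),
            "gyro": ex.sensor.gyro.tolist(),
            "orientation": ex.sensor.orientation.tolist(),
        },
    }
    if ex.spiral is not None:
        sp = ex.spiral
        obj["spiral"] = {"center_x": sp.center_x, "center_y": sp.center_y,
                         "pitch": sp.pitch, "n_turns": sp.n_turns,
                         "chirality": sp.chirality, "stroke_width": sp.stroke_width}
    return obj


def _require(obj: dict, key: str, where: str):
    if key not in obj:
        raise SchemaError(f"{where}: missing required field {key!r}")
    return obj[key]


def _execution_from_obj(obj: dict, where: str, scale: float = 1.0) -> TaskExecution:
    task = _require(obj, "task", where)
    subs = [SubEvent(int(e["index"]), float(e["t_appear"]), float(e["t_input"]),
                     float(e["target_x"]) * scale, float(e["target_y"]) * scale,
                     bool(e.get("success", True)))
            for e in _require(obj, "sub_events", where)]
    tch = _require(obj, "touch", where)
    touch = TouchStream(_nan_to_num(tch["t"]),
                        _nan_to_num(tch["x"]) * scale,
                        _nan_to_num(tch["y"]) * scale,
                        np.asarray(tch["phase"]),
                        _nan_to_num(tch["area"]))
    sen = _require(obj, "sensor", where)

    def _mat(rows) -> np.ndarray:
        return np.array([[np.nan if v is None else v for v in r] for r in rows],
                        dtype=float).reshape(-1, 3)

    sensor = InertialStream(_nan_to_num(sen["t"]), _mat(sen["accel"]),
                            _mat(sen["gyro"]), _mat(sen["orientation"]))
    spiral = None
    if "spiral" in obj:
        sp = obj["spiral"]
        spiral = SpiralSpec(center_x=float(sp["center_x"]) * scale,
                            center_y=float(sp["center_y"]) * scale,
                            pitch=float(sp["pitch"]) * scale,
                            n_turns=float(sp["n_turns"]),
                            chirality=sp["chirality"],
                            stroke_width=float(sp["stroke_width"]) * scale)
    return TaskExecution(task, subs, touch, sensor,
                         float(_require(obj, "elapsed", where)), spiral=spiral)


def _session_to_obj(s: SessionSet) -> dict:
    return {
        "participant_id": s.participant_id, "day": s.day, "set_index": s.set_index,
        "hand": s.hand, "handedness": s.handedness,
        "grip": {"reading_1": s.grip.reading_1, "reading_2": s.grip.reading_2},
        "executions": {task: _execution_to_obj(ex)
                       for task, ex in sorted(s.executions.items())},
    }


def _session_from_obj(obj: dict, scale: float) -> SessionSet:
    pid = _require(obj, "participant_id", "session record")
    where = (f"participant={pid} day={obj.get('day')} "
             f"set={obj.get('set_index')}")
    grip_obj = _require(obj, "grip", where)
    grip = GripMeasurement(float(_require(grip_obj, "reading_1", where)),
                           float(_require(grip_obj, "reading_2", where)))
    executions = {task: _execution_from_obj(ex_obj, f"{where} task={task}", scale)
                  for task, ex_obj in _require(obj, "executions", where).items()}
    return SessionSet(str(pid), int(_require(obj, "day", where)),
                      int(_require(obj, "set_index", where)), grip, executions,
                      hand=obj.get("hand", "right"),
                      handedness=obj.get("handedness", "dominant"))


def write_sessions(sessions: Iterable[SessionSet], path: str | Path,
                   screen: ScreenSpec | None = None,
                   device: str = "synthetic") -> None:
    """Write a JSONL session log (header line first)."""
    screen = screen or ScreenSpec()
    path = Path(path)
    header = {"schema": SCHEMA_VERSION, "device": device,
              "screen_width_mm": screen.width_mm,
              "screen_height_mm": screen.height_mm,
              "sensor_rate_hz": 60.0, "units": "mm"}
    with path.open("w", encoding="utf-8") as f:
        f.write(json.dumps(header, separators=(",", ":")) + "\n")
        for s in sort_sessions(sessions):
            obj = _round_floats(_session_to_obj(s))
            f.write(json.dumps(obj, separators=(",", ":")) + "\n")


def read_sessions(path: str | Path, format: str = "jsonl") -> list[SessionSet]:
    """Read and validate a session log; sessions ordered (participant, day, set)."""
    path = Path(path)
    if not path.exists():
        raise UsageError(f"no such session log: {path}")
    if format == "jsonl":
        sessions, screen = _read_jsonl(path)
    elif format == "csv-bundle":
        sessions, screen = _read_csv_bundle(path)
    else:
        raise UsageError(f"unknown session-log format {format!r}")
    for s in sessions:
        s.validate(screen, allow_missing=True)
    return sort_sessions(sessions)


def _read_jsonl(path: Path):
    with path.open(encoding="utf-8") as f:
        first = f.readline()
        if not first.strip():
            raise SchemaError(f"{path}: empty session log")
        header = json.loads(first)
        if header.get("schema") != SCHEMA_VERSION:
            raise SchemaError(f"{path}: unsupported schema {header.get('schema')!r}")
        units = header.get("units", "mm")
        if units == "mm":
            scale = 1.0
        elif units == "px":
            dpm = header.get("dots_per_mm")
            if not dpm:
                raise SchemaError(f"{path}: pixel units require dots_per_mm")
            scale = 1.0 / float(dpm)
        else:
            raise SchemaError(f"{path}: unknown units {units!r}")
        screen = ScreenSpec(float(header["screen_width_mm"]),
                            float(header["screen_height_mm"]))
        sessions = []
        for lineno, line in enumerate(f, start=2):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as e:
                raise SchemaError(f"{path}:{lineno}: invalid JSON: {e}") from e
            sessions.append(_session_from_obj(obj, scale))
    return sessions, screen


# -- csv-bundle dialect -------------------------------------------------------

_BUNDLE_FILES = ("sets.csv", "subevents.csv", "touch.csv", "sensor.csv")


def write_sessions_csv_bundle(sessions: Iterable[SessionSet],
                              directory: str | Path,
                              screen: ScreenSpec | None = None) -> None:
    """Write the csv-bundle dialect: four relational CSV tables plus header.json."""
    screen = screen or ScreenSpec()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sets_rows, sub_rows, touch_rows, sensor_rows = [], [], [], []
    for s in sort_sessions(sessions):
        key = (s.participant_id, s.day, s.set_index)
        sets_rows.append((*key, s.hand, s.handedness,
                          s.grip.reading_1, s.grip.reading_2))
        for task, ex in sorted(s.executions.items()):
            sp = ex.spiral
            sub_rows.extend((*key, task, e.index, e.t_appear, e.t_input,
                             e.target_x, e.target_y, int(e.success), ex.elapsed,
                             *((sp.center_x, sp.center_y, sp.pitch, sp.n_turns,
                                sp.stroke_width, sp.chirality) if sp else
                               (np.nan,) * 5 + ("",)))
                            for e in ex.sub_events)
            tch = ex.touch
            touch_rows.extend(zip([key[0]] * len(tch), [key[1]] * len(tch),
                                  [key[2]] * len(tch), [task] * len(tch),
                                  tch.t, tch.x, tch.y, tch.phase,
                                  tch.contact_area))
            sen = ex.sensor
            m = sen.matrix()
            sensor_rows.extend(
                (key[0], key[1], key[2], task, sen.t[i], *m[i])
                for i in range(len(sen)))
    pd.DataFrame(sets_rows, columns=["participant_id", "day", "set_index", "hand",
                                     "handedness", "reading_1", "reading_2"]
                 ).to_csv(directory / "sets.csv", index=False)
    pd.DataFrame(sub_rows, columns=["participant_id", "day", "set_index", "task",
                                    "index", "t_appear", "t_input", "target_x",
                                    "target_y", "success", "elapsed",
                                    "spiral_center_x", "spiral_center_y",
                                    "spiral_pitch", "spiral_n_turns",
                                    "spiral_stroke_width", "spiral_chirality"]
                 ).to_csv(directory / "subevents.csv", index=False)
    pd.DataFrame(touch_rows, columns=["participant_id", "day", "set_index", "task",
                                      "t", "x", "y", "phase", "area"]
                 ).to_csv(directory / "touch.csv", index=False)
    pd.DataFrame(sensor_rows, columns=["participant_id", "day", "set_index",
                                       "task", "t", "acc_x", "acc_y", "acc_z",
                                       "gyr_x", "gyr_y", "gyr_z",
                                       "ori_x", "ori_y", "ori_z"]
                 ).to_csv(directory / "sensor.csv", index=False)
    (directory / "header.json").write_text(json.dumps(
        {"schema": SCHEMA_VERSION, "screen_width_mm": screen.width_mm,
         "screen_height_mm": screen.height_mm, "sensor_rate_hz": 60.0,
         "units": "mm"}))


def _read_csv_bundle(directory: Path):
    for fname in _BUNDLE_FILES:
        if not (directory / fname).exists():
            raise SchemaError(f"csv-bundle missing {fname} in {directory}")
    header = json.loads((directory / "header.json").read_text()) \
        if (directory / "header.json").exists() else {}
    screen = ScreenSpec(float(header.get("screen_width_mm", 72.9)),
                        float(header.get("screen_height_mm", 152.0)))
    sets = pd.read_csv(directory / "sets.csv")
    subs = pd.read_csv(directory / "subevents.csv")
    touch = pd.read_csv(directory / "touch.csv")
    sensor = pd.read_csv(directory / "sensor.csv")
    key_cols = ["participant_id", "day", "set_index"]
    sub_g = subs.groupby(key_cols + ["task"])
    touch_g = touch.groupby(key_cols + ["task"])
    sensor_g = sensor.groupby(key_cols + ["task"])
    sessions = []
    for _, row in sets.iterrows():
        key = (row["participant_id"], int(row["day"]), int(row["set_index"]))
        grip = GripMeasurement(float(row["reading_1"]), float(row["reading_2"]))
        executions = {}
        for task in ("tap", "flick", "drag"):
            gk = (*key, task)
            if gk not in sub_g.groups:
                raise SchemaError(f"csv-bundle: missing {task} sub-events for {key}")
            sdf = sub_g.get_group(gk).sort_values("index")
            tdf = touch_g.get_group(gk).sort_values("t")
            ndf = sensor_g.get_group(gk).sort_values("t")
            spiral = None
            if task == "drag" and isinstance(sdf.iloc[0]["spiral_chirality"], str):
                r0 = sdf.iloc[0]
                spiral = SpiralSpec(float(r0["spiral_center_x"]),
                                    float(r0["spiral_center_y"]),
                                    float(r0["spiral_pitch"]),
                                    float(r0["spiral_n_turns"]),
                                    r0["spiral_chirality"],
                                    float(r0["spiral_stroke_width"]))
            subs_list = [SubEvent(int(r["index"]), float(r["t_appear"]),
                                  float(r["t_input"]), float(r["target_x"]),
                                  float(r["target_y"]), bool(r["success"]))
                         for _, r in sdf.iterrows()]
            executions[task] = TaskExecution(
                task, subs_list,
                TouchStream(tdf["t"].to_numpy(), tdf["x"].to_numpy(),
                            tdf["y"].to_numpy(), tdf["phase"].to_numpy(),
                            tdf["area"].to_numpy()),
                InertialStream(ndf["t"].to_numpy(),
                               ndf[["acc_x", "acc_y", "acc_z"]].to_numpy(),
                               ndf[["gyr_x", "gyr_y", "gyr_z"]].to_numpy(),
                               ndf[["ori_x", "ori_y", "ori_z"]].to_numpy()),
                float(sdf.iloc[0]["elapsed"]), spiral=spiral)
        sessions.append(SessionSet(str(row["participant_id"]), int(row["day"]),
                                   int(row["set_index"]), grip, executions,
                                   hand=row.get("hand", "right"),
                                   handedness=row.get("handedness", "dominant")))
    return sessions, screen


# -- feature matrices ---------------------------------------------------------

def write_feature_matrix(rows, path: str | Path) -> None:
    """Write a feature matrix CSV (grip_kg last, schema hash in a comment line).

    ``rows`` is either a list of FeatureVector sharing one schema or a
    DataFrame from :func:`gripsense.features.build_feature_table`.
    """
    path = Path(path)
    scope = None
    if isinstance(rows, pd.DataFrame):
        df = rows
        names = feature_columns(df)
        sh = df.attrs.get("schema_hash") or schema_hash(names)
        scope = df.attrs.get("task_scope")
    else:
        rows = list(rows)
        names = None
        recs = []
        for fv in rows:
            if names is None:
                names = list(fv.names)
                scope = fv.task_scope
            elif list(fv.names) != names:
                extra = sorted(set(fv.names) ^ set(names))
                raise UsageError(f"heterogeneous feature names, mismatch: {extra}")
            recs.append((fv.participant_id, fv.day, fv.set_index,
                         *fv.values, fv.grip_kg))
        names = names or []
        df = pd.DataFrame(recs, columns=[*KEY_COLUMNS, *names, TARGET_COLUMN])
        sh = schema_hash(names)
    with path.open("w", encoding="utf-8", newline="") as f:
        f.write(f"# gripsense-features/1 schema_hash={sh}"
                f"{f' scope={scope}' if scope else ''}\n")
        df.to_csv(f, index=False, lineterminator="\n", float_format="%.17g")


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature matrix CSV back into a keyed DataFrame."""
    path = Path(path)
    with path.open(encoding="utf-8") as f:
        first = f.readline()
    sh = scope = None
    if first.startswith("#"):
        for tok in first.split():
            if tok.startswith("schema_hash="):
                sh = tok.split("=", 1)[1]
            elif tok.startswith("scope="):
                scope = tok.split("=", 1)[1]
    df = pd.read_csv(path, comment="#")
    names = feature_columns(df)
    expected = schema_hash(names)
    if sh is not None and sh != expected:
        raise ValidationError(
            f"feature matrix schema hash {sh} does not match columns ({expected})")
    df.attrs["schema_hash"] = expected
    if scope:
        df.attrs["task_scope"] = scope
    return df


# -- reports ------------------------------------------------------------------

def write_report(report_obj: dict, json_path: str | Path,
                 markdown_path: str | Path | None = None) -> None:
    Path(json_path).write_text(json.dumps(_round_floats(report_obj), indent=2,
                                          sort_keys=True) + "\n")
    if markdown_path is not None:
        from gripsense.evaluation import render_markdown
        Path(markdown_path).write_text(render_markdown(report_obj))
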