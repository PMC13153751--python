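"""Synthetic cohort generator.

Emulates the study design — by default 21 participants x 5 days x 10
consecutive sets, each set pairing a dynamometer ground truth with one
tap, one flick and one drag execution — with the statistical structure
the downstream analysis assumes:

* latent grip for participant i, day d, set s:
  ``G = mu + u_i + v_id - fatigue_slope * (s - 1)``, truncated at 1 kg,
  with between-user offsets ``u_i ~ N(0, user_sd^2)`` and day offsets
  ``v_id ~ N(0, day_sd^2)``; the within-day decline models the fatigue
  intentionally induced by squeezing the dynamometer before every set;
* two dynamometer readings = G plus independent measurement noise;
* grip-coupled behavior: each behavioral channel c (timings, spatial and
  tracing errors, contact area, device jitter amplitude) is driven by
  ``b = coupling * (-z + w_ic) + (1 - coupling) * eps`` where
  ``z = (G - mu) / grip_population_sd`` is standardized grip, ``w_ic`` is
  a per-user idiosyncratic offset in how grip maps to that channel, and
  ``eps`` is fresh noise.  Weaker grip (negative z) means slower, less
  accurate, shakier interaction.  At ``coupling = 0`` behavior carries no
  information about grip at all.

Seeding is counter-based: every participant / set draws from a
``SeedSequence(master, spawn_key=...)`` stream, so enlarging the cohort
never perturbs previously generated participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from gripsense.errors import ConfigError
from gripsense.geometry import (
    SpiralSpec,
    sample_flick_layout,
    sample_tap_targets,
    spiral_length,
    theta_at_arc_fraction,
)
from gripsense.session import (
    GripMeasurement,
    InertialStream,
    ScreenSpec,
    SessionSet,
    SubEvent,
    TaskExecution,
    TouchStream,
)

FS = 60.0

#: log-scale sensitivity of each behavioral channel to its driver
_SENS = {
    "tap_elim": 0.18, "tap_dur": 0.25, "tap_err": 0.30,
    "flick_react": 0.18, "flick_dur": 0.25, "flick_ang": 0.30,
    "drag_dur": 0.15, "drag_err": 0.30,
    "area": 0.15, "jitter": 0.40,
}
_CHANNELS = tuple(_SENS)

#: baseline jitter amplitude per sensor group (accel m/s^2, gyro rad/s, ori deg)
_JITTER_BASE = np.repeat([0.25, 0.08, 1.2], 3)
#: white measurement-noise scale per group, multiplied by sensor_noise_sd
_WHITE_BASE = np.repeat([1.0, 0.3, 5.0], 3)
#: share of the behavioral noise that is a per-execution state (momentary
#: attention/fatigue during that one task run) rather than per-sub-event
#: scatter; shared noise does not average out within a task, so combining
#: tasks carries independent information
_EXEC_NOISE_SHARE = 0.8
#: weight of a scalar day-level state shared by every behavioral channel
#: (daily condition: sleep, mood, arm fatigue), on top of the independent
#: per-channel day offsets
_DAY_STATE_SHARE = 0.3


@dataclass(frozen=True)
class CohortSpec:
    """Study-design and generative parameters for one synthetic cohort."""

    n_participants: int = 21
    n_days: int = 5
    sets_per_day: int = 10
    grip_population_mean: float = 30.0   # kg; cohort concentrated ~25-35 kg
    grip_population_sd: float = 5.0      # kg; scale for standardizing grip
    user_sd: float = 4.0                 # kg between users
    day_sd: float = 1.0                  # kg between days within a user
    fatigue_slope: float = 0.3           # kg decline per consecutive set
    measurement_sd: float = 0.5          # kg dynamometer reading noise
    coupling: float = 0.8                # grip->behavior signal fraction
    idiosyncrasy_sd: float = 0.5         # per-user offset in the behavior link
    day_idiosyncrasy_sd: float = 0.15    # per-day offset in the behavior link
    sensor_noise_sd: float = 0.05        # white sensor noise scale
    sensor_dropout: float = 0.01         # fraction of sensor values missing
    rng_seed: int = 0
    screen: ScreenSpec = field(default_factory=ScreenSpec)

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_days, self.sets_per_day) < 1:
            raise ConfigError("cohort counts must be >= 1")
        for name in ("grip_population_sd", "user_sd", "day_sd", "measurement_sd",
                     "idiosyncrasy_sd", "day_idiosyncrasy_sd", "sensor_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.coupling <= 1.0:
            raise ConfigError("coupling must be in [0, 1]")
        if not 0.0 <= self.sensor_dropout < 1.0:
            raise ConfigError("sensor_dropout must be in [0, 1)")


def _rng(spec: CohortSpec, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.rng_seed, spawn_key=key))


def _driver(coupling: float, z: float, w: float, eps, eta: float = 0.0
            ) -> np.ndarray:
    rho = _EXEC_NOISE_SHARE
    noise = rho * eta + np.sqrt(1.0 - rho**2) * np.asarray(eps)
    return coupling * (-z + w) + (1.0 - coupling) * noise


def _smooth_noise(rng: np.random.Generator, n: int, ncols: int,
                  window: int = 5) -> np.ndarray:
    white = rng.standard_normal((n + window - 1, ncols))
    c = np.cumsum(white, axis=0)
    out = (c[window - 1:] - np.vstack([np.zeros((1, ncols)), c[:-window]])) / window
    return out * np.sqrt(window)  # keep unit variance after averaging


def _sensor_stream(rng: np.random.Generator, elapsed: float, base: np.ndarray,
                   jitter_factor: float, spec: CohortSpec) -> InertialStream:
    n = int(np.ceil(elapsed * FS)) + 1
    t = np.arange(n) / FS
    m = (base
         + _smooth_noise(rng, n, 9) * (_JITTER_BASE * jitter_factor)
         + rng.standard_normal((n, 9)) * (_WHITE_BASE * spec.sensor_noise_sd))
    if spec.sensor_dropout > 0:
        mask = rng.random((n, 9)) < spec.sensor_dropout
        # keep the first and last frame intact so interpolation has anchors
        mask[0] = mask[-1] = False
        m = np.where(mask, np.nan, m)
    return InertialStream.from_matrix(t, m)


def _stroke_touch(t0: float, dur: float, path_fn, area: float,
                  rng: np.random.Generator, n_min: int = 2):
    """Columnar samples for one stroke; path_fn maps u in [0,1] -> (x, y)."""
    n = max(n_min, int(round(dur * FS)) + 1)
    u = np.linspace(0.0, 1.0, n)
    x, y = path_fn(u)
    t = t0 + u * dur
    phase = np.array(["down"] + ["move"] * (n - 2) + ["up"]) if n > 1 \
        else np.array(["down"])
    a = np.clip(area + 0.01 * rng.standard_normal(n), 1e-3, None)
    return t, x, y, phase, a


def _concat_touch(parts) -> TouchStream:
    t, x, y, ph, a = (np.concatenate(cols) for cols in zip(*parts))
    return TouchStream(t, x, y, ph, a)


def _clip_to_screen(x, y, screen: ScreenSpec):
    return (np.clip(x, 0.0, screen.width_mm), np.clip(y, 0.0, screen.height_mm))


def _jitter_factor(rng: np.random.Generator, c: float, z: float, w: dict,
                   eta: float) -> float:
    return float(np.exp(_SENS["jitter"]
                        * _driver(c, z, w["jitter"], rng.standard_normal(), eta)))


def _tap_execution(rng: np.random.Generator, z: float, w: dict, spec: CohortSpec,
                   base_sensor: np.ndarray) -> TaskExecution:
    c = spec.coupling
    n_ev = 10
    eta = float(rng.standard_normal())  # per-execution behavioral state
    jitter_factor = _jitter_factor(rng, c, z, w, eta)
    elim = np.clip(0.45 * np.exp(_SENS["tap_elim"]
                   * _driver(c, z, w["tap_elim"], rng.standard_normal(n_ev), eta)),
                   0.15, 2.5)
    dur = np.clip(0.09 * np.exp(_SENS["tap_dur"]
                  * _driver(c, z, w["tap_dur"], rng.standard_normal(n_ev), eta)),
                  0.03, 0.5)
    err = 1.6 * np.exp(_SENS["tap_err"]
                       * _driver(c, z, w["tap_err"], rng.standard_normal(n_ev), eta))
    area = 0.25 * np.exp(_SENS["area"]
                         * _driver(c, -z, w["area"], rng.standard_normal(n_ev), eta))
    targets = sample_tap_targets(n_ev, spec.screen, int(rng.integers(2**31)))

    sub_events, parts = [], []
    t_appear = 0.0
    for j in range(n_ev):
        t_input = t_appear + float(elim[j])
        ang = rng.uniform(0, 2 * np.pi)
        px = targets[j].x + err[j] * np.cos(ang)
        py = targets[j].y + err[j] * np.sin(ang)

        def path(u, px=px, py=py):
            wob = 0.05 * np.sin(2 * np.pi * u)
            return _clip_to_screen(px + wob, py + wob, spec.screen)

        parts.append(_stroke_touch(t_input, float(dur[j]), path, float(area[j]), rng))
        sub_events.append(SubEvent(j + 1, t_appear, t_input,
                                   targets[j].x, targets[j].y, True))
        t_appear = t_input + float(dur[j]) + 0.05
    elapsed = t_appear + 0.05
    return TaskExecution("tap", sub_events, _concat_touch(parts),
                         _sensor_stream(rng, elapsed, base_sensor,
                                        jitter_factor, spec), elapsed)


def _flick_execution(rng: np.random.Generator, z: float, w: dict, spec: CohortSpec,
                     base_sensor: np.ndarray) -> TaskExecution:
    c = spec.coupling
    n_ev = 10
    eta = float(rng.standard_normal())
    jitter_factor = _jitter_factor(rng, c, z, w, eta)
    react = np.clip(0.50 * np.exp(_SENS["flick_react"]
                    * _driver(c, z, w["flick_react"], rng.standard_normal(n_ev), eta)),
                    0.15, 2.5)
    dur = np.clip(0.12 * np.exp(_SENS["flick_dur"]
                  * _driver(c, z, w["flick_dur"], rng.standard_normal(n_ev), eta)),
                  0.05, 0.6)
    ang_sd = np.deg2rad(8.0) * np.exp(_SENS["flick_ang"]
        * _driver(c, z, w["flick_ang"], rng.standard_normal(n_ev), eta))
    area = 0.25 * np.exp(_SENS["area"]
                         * _driver(c, -z, w["area"], rng.standard_normal(n_ev), eta))

    sub_events, parts = [], []
    t_appear = 0.0
    for j in range(n_ev):
        ball, goal = sample_flick_layout(rng, spec.screen)
        aim = np.arctan2(goal.y - ball.y, goal.x - ball.x) \
            + rng.normal(0.0, float(ang_sd[j]))
        length = 15.0 + rng.uniform(0.0, 8.0)
        t_input = t_appear + float(react[j]) + float(dur[j])

        def path(u, bx=ball.x, by=ball.y, aim=aim, length=length):
            lateral = 0.3 * np.sin(np.pi * u)
            x = bx + u * length * np.cos(aim) - lateral * np.sin(aim)
            y = by + u * length * np.sin(aim) + lateral * np.cos(aim)
            return _clip_to_screen(x, y, spec.screen)

        parts.append(_stroke_touch(t_input - float(dur[j]), float(dur[j]), path,
                                   float(area[j]), rng, n_min=3))
        sub_events.append(SubEvent(j + 1, t_appear, t_input, goal.x, goal.y, True))
        t_appear = t_input + 0.12
    elapsed = t_appear + 0.05
    return TaskExecution("flick", sub_events, _concat_touch(parts),
                         _sensor_stream(rng, elapsed, base_sensor,
                                        jitter_factor, spec), elapsed)


def _drag_execution(rng: np.random.Generator, z: float, w: dict, spec: CohortSpec,
                    base_sensor: np.ndarray, hand: str) -> TaskExecution:
    c = spec.coupling
    eta = float(rng.standard_normal())
    jitter_factor = _jitter_factor(rng, c, z, w, eta)
    dur = float(np.clip(3.6 * np.exp(_SENS["drag_dur"]
                        * _driver(c, z, w["drag_dur"], rng.standard_normal(), eta)),
                        1.5, 10.0))
    err_scale = 0.7 * np.exp(_SENS["drag_err"]
                             * _driver(c, z, w["drag_err"], rng.standard_normal(), eta))
    area = 0.25 * np.exp(_SENS["area"]
                         * _driver(c, -z, w["area"], rng.standard_normal(), eta))
    spiral = SpiralSpec(center_x=spec.screen.width_mm / 2,
                        center_y=spec.screen.height_mm / 2,
                        chirality="clockwise" if hand == "right"
                        else "counterclockwise")
    if not spiral.fits(spec.screen):
        raise ConfigError("default spiral does not fit the screen")

    n = max(32, int(round(dur * FS)) + 1)
    t = np.linspace(0.0, dur, n)
    gamma = float(np.exp(rng.normal(0.0, 0.1)))   # gentle speed profile
    s = (t / dur) ** gamma
    theta = theta_at_arc_fraction(spiral, s)
    cx, cy = spiral.point_at_theta(theta)
    # unit normal to the curve for radial tracing noise
    dx = np.gradient(cx)
    dy = np.gradient(cy)
    nrm = np.hypot(dx, dy)
    nrm[nrm == 0] = 1.0
    noise = _smooth_noise(rng, n, 1)[:, 0] * float(err_scale)
    x = cx + noise * (-dy / nrm)
    y = cy + noise * (dx / nrm)
    x, y = _clip_to_screen(x, y, spec.screen)
    phase = np.array(["down"] + ["move"] * (n - 2) + ["up"])
    a = np.clip(area + 0.01 * rng.standard_normal(n), 1e-3, None)

    elapsed = dur + 0.1
    sub = SubEvent(1, 0.0, dur / 2, spiral.center_x, spiral.center_y, True)
    return TaskExecution("drag", [sub], TouchStream(t, x, y, phase, a),
                         _sensor_stream(rng, elapsed, base_sensor,
                                        jitter_factor, spec),
                         elapsed, spiral=spiral)


def generate_cohort(spec: CohortSpec) -> list[SessionSet]:
    """Generate the full cohort, ordered (participant, day, set)."""
    mu = spec.grip_population_mean
    floor_grip = mu - spec.fatigue_slope * (spec.sets_per_day - 1)
    if floor_grip <= 1.0:
        warnings.warn("fatigue_slope drives the average participant's grip to "
                      "the 1 kg truncation floor within a day", stacklevel=2)

    sessions: list[SessionSet] = []
    for i in range(spec.n_participants):
        rng_p = _rng(spec, i)
        pid = f"P{i + 1:02d}"
        u_i = rng_p.normal(0.0, spec.user_sd)
        w = {ch: rng_p.normal(0.0, spec.idiosyncrasy_sd) for ch in _CHANNELS}
        for d in range(1, spec.n_days + 1):
            rng_d = _rng(spec, i, d)
            v_id = rng_d.normal(0.0, spec.day_sd)
            w_day = {ch: rng_d.normal(0.0, spec.day_idiosyncrasy_sd)
                     for ch in _CHANNELS}
            day_state = float(rng_d.standard_normal())
            w_eff = {ch: w[ch] + w_day[ch] + _DAY_STATE_SHARE * day_state
                     for ch in _CHANNELS}
            for s in range(1, spec.sets_per_day + 1):
                rng_s = _rng(spec, i, d, s)
                G = max(1.0, mu + u_i + v_id - spec.fatigue_slope * (s - 1))
                r1 = max(0.0, G + rng_s.normal(0.0, spec.measurement_sd))
                r2 = max(0.0, G + rng_s.normal(0.0, spec.measurement_sd))
                z = (G - mu) / spec.grip_population_sd
                # posture baseline re-drawn every set: how the phone is held
                # varies between sets and carries no stable user signature
                base_sensor = np.concatenate([
                    np.array([0.4, 0.3, 9.7]) + rng_s.normal(0.0, 0.3, 3),
                    np.zeros(3),
                    np.array([40.0, 0.0, 5.0]) + rng_s.normal(0.0, 8.0, 3),
                ])
                executions = {
                    "tap": _tap_execution(rng_s, z, w_eff, spec, base_sensor),
                    "flick": _flick_execution(rng_s, z, w_eff, spec, base_sensor),
                    "drag": _drag_execution(rng_s, z, w_eff, spec, base_sensor,
                                            "right"),
                }
                sessions.append(SessionSet(pid, d, s,
                                           GripMeasurement(r1, r2), executions))
    return sessions


def describe_cohort(sessions: list[SessionSet]) -> dict:
    """Summary statistics used to verify generator calibration.

    Returns record counts, per-participant grip mean/sd, and the pooled
    within-participant-day slope of grip across consecutive sets (kg per
    set; a fatigue estimate).  The slope is flagged undefined when no
    participant-day has at least two sets.
    """
    if not sessions:
        raise ConfigError("describe_cohort needs a nonempty collection")
    rows = [(s.participant_id, s.day, s.set_index, s.grip.ground_truth)
            for s in sessions]
    pids = sorted({r[0] for r in rows})
    per_participant = {}
    for pid in pids:
        g = np.array([r[3] for r in rows if r[0] == pid])
        per_participant[pid] = {"n": int(g.size), "mean": float(g.mean()),
                                "sd": float(g.std(ddof=1)) if g.size > 1 else 0.0}
    # pooled OLS slope on (set_index, grip) after demeaning each participant-day
    xs, ys = [], []
    for pid in pids:
        days = sorted({r[1] for r in rows if r[0] == pid})
        for d in days:
            grp = [(r[2], r[3]) for r in rows if r[0] == pid and r[1] == d]
            if len(grp) < 2:
                continue
            sx = np.array([g[0] for g in grp], dtype=float)
            sy = np.array([g[1] for g in grp], dtype=float)
            xs.append(sx - sx.mean())
            ys.append(sy - sy.mean())
    if xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        slope = float(x @ y / (x @ x))
        slope_defined = True
    else:
        slope, slope_defined = float("nan"), False
    return {
        "n_sets": len(sessions),
        "n_participants": len(pids),
        "per_participant": per_participant,
        "set_slope_kg_per_set": slope,
        "set_slope_defined": slope_defined,
    }
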