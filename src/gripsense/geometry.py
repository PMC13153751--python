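"""Task geometry: target layouts, the drag spiral, left-hand mirroring.

The drag task traces an Archimedean spiral r(theta) = pitch * theta / (2*pi)
outward from the screen center.  Only the stroke width (4.4 mm) and the
direction convention (clockwise for the right hand) are fixed by the task
design; pitch and turn count are configurable with defaults that fit the
72.9 mm screen width with margin.

Chirality is defined in screen coordinates (y down): a ``clockwise``
spiral has its polar angle increasing in the +y-from-+x sense, which reads
as clockwise on a conventional y-up plot and matches how a right thumb
naturally curls outward.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from gripsense.errors import ConfigError, UsageError
from gripsense.session import ScreenSpec, SubEvent, TaskExecution

TAP_TARGET_DIAMETER_MM = 14.6
FLICK_BALL_DIAMETER_MM = 7.3
FLICK_GOAL_DIAMETER_MM = 14.6
SPIRAL_STROKE_WIDTH_MM = 4.4

#: flick ball-to-goal distance (mm); unspecified by the task design,
#: fixed so flick kinematics stay comparable across sub-events.
FLICK_GOAL_DISTANCE_MM = 25.0


@dataclass(frozen=True)
class TargetSpec:
    """An on-screen circular target."""

    x: float
    y: float
    diameter: float
    kind: str  # tap_target | flick_ball | flick_goal


@dataclass(frozen=True)
class SpiralSpec:
    """Archimedean spiral centerline for the drag task."""

    center_x: float = 72.9 / 2
    center_y: float = 152.0 / 2
    pitch: float = 8.0          # mm of radius growth per full turn
    n_turns: float = 3.0
    chirality: str = "clockwise"
    stroke_width: float = SPIRAL_STROKE_WIDTH_MM

    def __post_init__(self) -> None:
        if self.pitch <= 0 or self.n_turns <= 0 or self.stroke_width <= 0:
            raise ConfigError("spiral pitch, n_turns and stroke_width must be > 0")
        if self.chirality not in ("clockwise", "counterclockwise"):
            raise ConfigError(f"unknown chirality {self.chirality!r}")

    @property
    def a(self) -> float:
        """Radius growth per radian."""
        return self.pitch / (2 * np.pi)

    @property
    def theta_max(self) -> float:
        return 2 * np.pi * self.n_turns

    @property
    def outer_radius(self) -> float:
        return self.pitch * self.n_turns

    @property
    def sign(self) -> float:
        return 1.0 if self.chirality == "clockwise" else -1.0

    def fits(self, screen: ScreenSpec) -> bool:
        r = self.outer_radius + self.stroke_width / 2
        return (r <= self.center_x <= screen.width_mm - r
                and r <= self.center_y <= screen.height_mm - r)

    def point_at_theta(self, theta):
        """Centerline point(s) at polar angle theta (vectorized)."""
        theta = np.asarray(theta, dtype=float)
        r = self.a * theta
        x = self.center_x + r * np.cos(theta)
        y = self.center_y + self.sign * r * np.sin(theta)
        return x, y

    def mirrored(self, screen_width: float) -> "SpiralSpec":
        return replace(self,
                       center_x=screen_width - self.center_x,
                       chirality=("counterclockwise" if self.chirality == "clockwise"
                                  else "clockwise"))


def _arc_length(spec: SpiralSpec, theta) -> np.ndarray:
    """Closed-form arc length of r = a*theta from 0 to theta."""
    theta = np.asarray(theta, dtype=float)
    return 0.5 * spec.a * (theta * np.sqrt(1 + theta**2) + np.arcsinh(theta))


def spiral_length(spec: SpiralSpec) -> float:
    return float(_arc_length(spec, spec.theta_max))


def theta_at_arc_fraction(spec: SpiralSpec, s) -> np.ndarray:
    """Invert the arc-length map: s in [0, 1] -> theta (vectorized, Newton)."""
    s = np.asarray(s, dtype=float)
    target = s * spiral_length(spec)
    # ds/dtheta = a*sqrt(1+theta^2) > 0: Newton from a linear-in-length guess
    theta = np.sqrt(np.maximum(2 * target / spec.a, 0.0))  # small-theta asymptote
    theta = np.minimum(theta, spec.theta_max)
    for _ in range(50):
        f = _arc_length(spec, theta) - target
        df = spec.a * np.sqrt(1 + theta**2)
        step = f / df
        theta = np.clip(theta - step, 0.0, spec.theta_max)
        if np.max(np.abs(step)) < 1e-12:
            break
    return theta


def spiral_point(spec: SpiralSpec, s: float) -> tuple[float, float]:
    """Point on the centerline at arc-length fraction ``s`` in [0, 1].

    ``s = 0`` is the center, ``s = 1`` the outer endpoint at radius
    ``pitch * n_turns``.
    """
    if not 0.0 <= s <= 1.0:
        raise UsageError(f"arc-position parameter s must be in [0, 1], got {s}")
    theta = theta_at_arc_fraction(spec, s)
    x, y = spec.point_at_theta(theta)
    return float(x), float(y)


def spiral_polyline(spec: SpiralSpec, n: int = 4096,
                    by_arc_length: bool = False) -> np.ndarray:
    """(n, 2) polyline of the centerline, uniform in theta (or arc length)."""
    if by_arc_length:
        theta = theta_at_arc_fraction(spec, np.linspace(0.0, 1.0, n))
    else:
        theta = np.linspace(0.0, spec.theta_max, n)
    x, y = spec.point_at_theta(theta)
    return np.column_stack([x, y])


def distance_to_spiral(spec: SpiralSpec, points) -> np.ndarray | float:
    """Distance (mm) from point(s) to the nearest centerline point.

    Seeds each query with the best of a dense theta grid, then refines by
    a safeguarded Newton iteration on d/dtheta |p - c(theta)|^2, clamped
    to [0, theta_max].  Accurate to well under 0.01 mm.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    scalar = np.asarray(points).ndim == 1

    # grid fine enough that the seed lies in the basin of the true minimum
    n_grid = max(512, int(64 * spec.n_turns * 8))
    theta_grid = np.linspace(0.0, spec.theta_max, n_grid)
    gx, gy = spec.point_at_theta(theta_grid)

    best = np.empty(p.shape[0])
    theta = np.empty(p.shape[0])
    chunk = 2048
    for lo in range(0, p.shape[0], chunk):
        pp = p[lo:lo + chunk]
        d2 = (pp[:, 0:1] - gx) ** 2 + (pp[:, 1:2] - gy) ** 2
        j = np.argmin(d2, axis=1)
        theta[lo:lo + chunk] = theta_grid[j]
        best[lo:lo + chunk] = d2[np.arange(pp.shape[0]), j]

    a, sgn = spec.a, spec.sign
    px, py = p[:, 0] - spec.center_x, (p[:, 1] - spec.center_y) * sgn
    for _ in range(40):
        ct, st = np.cos(theta), np.sin(theta)
        cx, cy = a * theta * ct, a * theta * st
        dxc, dyc = a * (ct - theta * st), a * (st + theta * ct)
        rx, ry = cx - px, cy - py
        g = rx * dxc + ry * dyc                      # 0.5 * d/dtheta of d^2
        d2xc = a * (-2 * st - theta * ct)
        d2yc = a * (2 * ct - theta * st)
        h = dxc**2 + dyc**2 + rx * d2xc + ry * d2yc  # 0.5 * second derivative
        step = g / np.where(np.abs(h) > 1e-12, h, 1e-12)
        step = np.clip(step, -0.5, 0.5)              # trust region in radians
        new_theta = np.clip(theta - step, 0.0, spec.theta_max)
        ncx = a * new_theta * np.cos(new_theta)
        ncy = a * new_theta * np.sin(new_theta)
        nd2 = (ncx - px) ** 2 + (ncy - py) ** 2
        improved = nd2 <= best + 1e-15
        theta = np.where(improved, new_theta, theta)
        best = np.where(improved, nd2, best)
        if np.max(np.abs(step * improved)) < 1e-12:
            break

    d = np.sqrt(best)
    return float(d[0]) if scalar else d


def sample_tap_targets(n: int, screen: ScreenSpec, rng_seed: int) -> list[TargetSpec]:
    """Random tap-target layout: inside bounds, consecutive targets distinct.

    Consecutive centers are kept at least one target diameter apart and
    every target stays a full radius from the screen edge.  Deterministic
    for a given seed.
    """
    if n < 1:
        raise UsageError("n must be >= 1")
    radius = TAP_TARGET_DIAMETER_MM / 2
    lo = np.array([radius, radius])
    hi = np.array([screen.width_mm - radius, screen.height_mm - radius])
    if np.any(hi <= lo):
        raise ConfigError("screen too small for tap targets with edge margin")
    min_sep = TAP_TARGET_DIAMETER_MM
    rng = np.random.default_rng(rng_seed)
    targets: list[TargetSpec] = []
    prev = None
    for _ in range(n):
        for _attempt in range(1000):
            pos = rng.uniform(lo, hi)
            if prev is None or np.hypot(pos[0] - prev[0], pos[1] - prev[1]) >= min_sep:
                break
        else:  # screen guaranteed big enough above; defensive only
            raise ConfigError("could not place a tap target away from the previous one")
        targets.append(TargetSpec(float(pos[0]), float(pos[1]),
                                  TAP_TARGET_DIAMETER_MM, "tap_target"))
        prev = pos
    return targets


def sample_flick_layout(rng: np.random.Generator, screen: ScreenSpec
                        ) -> tuple[TargetSpec, TargetSpec]:
    """One flick ball plus its goal at a fixed 25 mm distance, both on-screen."""
    margin = FLICK_GOAL_DISTANCE_MM + FLICK_GOAL_DIAMETER_MM / 2
    lo = np.array([margin, margin])
    hi = np.array([screen.width_mm - margin, screen.height_mm - margin])
    if np.any(hi <= lo):
        raise ConfigError("screen too small for flick layout")
    ball = rng.uniform(lo, hi)
    ang = rng.uniform(0, 2 * np.pi)
    goal = ball + FLICK_GOAL_DISTANCE_MM * np.array([np.cos(ang), np.sin(ang)])
    return (TargetSpec(float(ball[0]), float(ball[1]), FLICK_BALL_DIAMETER_MM, "flick_ball"),
            TargetSpec(float(goal[0]), float(goal[1]), FLICK_GOAL_DIAMETER_MM, "flick_goal"))


def mirror_for_left_hand(execution: TaskExecution, screen_width: float) -> TaskExecution:
    """Map a left-hand execution into right-hand convention (or back).

    Horizontal touch and target coordinates become ``screen_width - x``
    and the spiral flips chirality (its center mirrors with it).  All
    timestamps and sensor streams are preserved exactly, so the transform
    is an involution.
    """
    out = execution.copy()
    out.touch.x = screen_width - out.touch.x
    out.sub_events = [
        SubEvent(e.index, e.t_appear, e.t_input,
                 screen_width - e.target_x, e.target_y, e.success)
        for e in execution.sub_events
    ]
    if out.spiral is not None:
        out.spiral = out.spiral.mirrored(screen_width)
    return out
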