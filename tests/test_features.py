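"""Behavioral features, windowed sensor statistics, unified assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gripsense.errors import DataError, UsageError
from gripsense.features import (
    FeatureVector,
    assemble_unified,
    build_feature_table,
    drag_features,
    extract_set_features,
    flick_features,
    sensor_stats,
    tap_features,
)
from gripsense.geometry import SpiralSpec, spiral_point
from gripsense.preprocessing import EventWindows
from gripsense.session import InertialStream, SubEvent, TaskExecution, TouchStream


def windows_from(pre, during, post):
    return EventWindows(pre=np.asarray(pre, float), during=np.asarray(during, float),
                        post=np.asarray(post, float), anchor_t=0.0)


class TestSensorStats:
    def test_constant_window(self):
        w = windows_from(np.full((10, 9), 4.2), np.full(9, 4.2),
                         np.full((10, 9), 4.2))
        out = sensor_stats(w)
        assert len(out) == 99
        assert out["pre_acc_x_range"] == 0.0
        assert out["post_gyr_z_absdiff_mean"] == 0.0
        assert out["pre_ori_y_mean"] == pytest.approx(4.2)
        assert out["during_acc_z"] == pytest.approx(4.2)

    def test_ramp_1_to_10(self):
        pre = np.tile(np.arange(1.0, 11.0)[:, None], (1, 9))
        w = windows_from(pre, np.zeros(9), np.zeros((10, 9)))
        out = sensor_stats(w)
        assert out["pre_acc_x_max"] == 10.0
        assert out["pre_acc_x_min"] == 1.0
        assert out["pre_acc_x_range"] == 9.0
        assert out["pre_acc_x_mean"] == pytest.approx(5.5)
        assert out["pre_acc_x_absdiff_mean"] == pytest.approx(1.0)

    def test_matches_naive_recomputation(self, rng):
        pre = rng.standard_normal((10, 9))
        post = rng.standard_normal((10, 9))
        during = rng.standard_normal(9)
        out = sensor_stats(windows_from(pre, during, post))
        chans = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z",
                 "ori_x", "ori_y", "ori_z")
        for win_name, rows in (("pre", pre), ("post", post)):
            for c, ch in enumerate(chans):
                col = rows[:, c]
                assert out[f"{win_name}_{ch}_max"] == pytest.approx(max(col))
                assert out[f"{win_name}_{ch}_min"] == pytest.approx(min(col))
                assert out[f"{win_name}_{ch}_range"] == pytest.approx(
                    max(col) - min(col))
                assert out[f"{win_name}_{ch}_mean"] == pytest.approx(
                    sum(col) / 10)
                diffs = [abs(col[i + 1] - col[i]) for i in range(9)]
                assert out[f"{win_name}_{ch}_absdiff_mean"] == pytest.approx(
                    sum(diffs) / 9)


def _blank_windows(n):
    return [windows_from(np.zeros((10, 9)), np.zeros(9), np.zeros((10, 9)))
            for _ in range(n)]


def _make_tap_execution(offsets):
    """10 taps with given (dx, dy) offsets from their targets."""
    subs, t_cols = [], []
    t = 0.0
    for j, (dx, dy) in enumerate(offsets):
        tx, ty = 30.0, 50.0 + j * 5
        t_in = t + 0.5
        subs.append(SubEvent(j + 1, t, t_in, tx, ty, True))
        t_cols.append(([t_in, t_in + 0.1], [tx + dx] * 2, [ty + dy] * 2,
                       ["down", "up"], [0.2, 0.2]))
        t = t_in + 0.2
    touch = TouchStream(*(np.concatenate([np.asarray(c[i]) for c in t_cols])
                          for i in range(5)))
    n = int(t * 60) + 2
    sensor = InertialStream.from_matrix(np.arange(n) / 60.0, np.zeros((n, 9)))
    return TaskExecution("tap", subs, touch, sensor, elapsed=t + 0.1)


class TestTapFeatures:
    def test_zero_spatial_error_at_center(self):
        ex = _make_tap_execution([(0.0, 0.0)] * 10)
        fv = tap_features(ex, _blank_windows(10))
        assert dict(zip(fv.names, fv.values))["spatial_error_mm"] == 0.0

    def test_three_four_five_offset(self):
        ex = _make_tap_execution([(3.0, 4.0)] * 10)
        fv = tap_features(ex, _blank_windows(10))
        vals = dict(zip(fv.names, fv.values))
        assert vals["spatial_error_mm"] == pytest.approx(5.0)
        assert vals["elimination_time_s"] == pytest.approx(0.5)
        assert vals["touch_duration_s"] == pytest.approx(0.1)

    def test_aggregate_is_mean_over_subevents(self):
        offsets = [(k + 1.0, 0.0) for k in range(10)]
        ex = _make_tap_execution(offsets)
        fv = tap_features(ex, _blank_windows(10))
        vals = dict(zip(fv.names, fv.values))
        assert vals["spatial_error_mm"] == pytest.approx(
            np.mean([k + 1.0 for k in range(10)]))

    def test_wrong_task_rejected(self, small_cohort):
        ex = small_cohort[0].executions["flick"]
        with pytest.raises(UsageError):
            tap_features(ex, _blank_windows(10))


def _make_flick_execution(vectors):
    subs, cols = [], []
    t = 0.0
    for j, (dx, dy) in enumerate(vectors):
        t_in = t + 0.6
        subs.append(SubEvent(j + 1, t, t_in, 40.0, 80.0, True))
        x0, y0 = 30.0, 70.0
        cols.append(([t_in - 0.1, t_in - 0.05, t_in],
                     [x0, x0 + dx / 2, x0 + dx], [y0, y0 + dy / 2, y0 + dy],
                     ["down", "move", "up"], [0.2, 0.2, 0.2]))
        t = t_in + 0.1
    touch = TouchStream(*(np.concatenate([np.asarray(c[i]) for c in cols])
                          for i in range(5)))
    n = int(t * 60) + 2
    sensor = InertialStream.from_matrix(np.arange(n) / 60.0, np.zeros((n, 9)))
    return TaskExecution("flick", subs, touch, sensor, elapsed=t + 0.1)


class TestFlickFeatures:
    def test_pure_rightward_strokes(self):
        ex = _make_flick_execution([(10.0, 0.0)] * 10)
        fv = flick_features(ex, _blank_windows(10))
        vals = dict(zip(fv.names, fv.values))
        assert vals["direction_x"] == pytest.approx(1.0)
        assert vals["direction_y"] == pytest.approx(0.0, abs=1e-12)

    def test_downward_stroke_is_positive_y(self):
        ex = _make_flick_execution([(0.0, 10.0)] * 10)
        fv = flick_features(ex, _blank_windows(10))
        vals = dict(zip(fv.names, fv.values))
        assert (vals["direction_x"], vals["direction_y"]) == \
            pytest.approx((0.0, 1.0), abs=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.floats(-20, 20), st.floats(-20, 20))
                    .filter(lambda v: np.hypot(*v) > 1e-3),
                    min_size=10, max_size=10))
    def test_single_stroke_directions_lie_on_unit_circle(self, vectors):
        ex = _make_flick_execution(vectors)
        strokes = [(3 * j, 3 * j + 2) for j in range(10)]
        for d, u in strokes:
            dx = ex.touch.x[u] - ex.touch.x[d]
            dy = ex.touch.y[u] - ex.touch.y[d]
            n = np.hypot(dx, dy)
            assert (dx / n) ** 2 + (dy / n) ** 2 == pytest.approx(1.0, abs=1e-9)

    def test_zero_length_strokes_excluded(self):
        vecs = [(10.0, 0.0)] * 9 + [(0.0, 0.0)]
        ex = _make_flick_execution(vecs)
        fv = flick_features(ex, _blank_windows(10))
        assert fv.excluded_sub_events == 1
        vals = dict(zip(fv.names, fv.values))
        assert vals["direction_x"] == pytest.approx(1.0)


def _make_drag_execution(pts, t_total=2.0, spec=None):
    pts = np.asarray(pts, float)
    n = pts.shape[0]
    t = np.linspace(0.0, t_total, n)
    touch = TouchStream(t, pts[:, 0], pts[:, 1],
                        ["down"] + ["move"] * (n - 2) + ["up"], np.full(n, 0.2))
    ns = int(t_total * 60) + 2
    sensor = InertialStream.from_matrix(np.arange(ns) / 60.0, np.zeros((ns, 9)))
    spec = spec or SpiralSpec(center_x=36.45, center_y=76.0)
    sub = SubEvent(1, 0.0, t_total / 2, spec.center_x, spec.center_y, True)
    return TaskExecution("drag", [sub], touch, sensor, t_total + 0.1,
                         spiral=spec), spec


class TestDragFeatures:
    def test_on_centerline_trace_has_zero_error(self):
        spec = SpiralSpec(center_x=36.45, center_y=76.0)
        pts = [spiral_point(spec, s) for s in np.linspace(0, 1, 80)]
        ex, spec = _make_drag_execution(pts, spec=spec)
        fv = drag_features(ex, spec, _blank_windows(1)[0])
        assert dict(zip(fv.names, fv.values))["tracing_error_mm"] <= 0.01

    def test_uniform_straight_line_kinematics(self):
        pts = np.column_stack([np.linspace(10, 50, 81), np.full(81, 60.0)])
        ex, spec = _make_drag_execution(pts, t_total=4.0)
        fv = drag_features(ex, spec, _blank_windows(1)[0])
        vals = dict(zip(fv.names, fv.values))
        assert vals["speed_mean_mm_s"] == pytest.approx(40.0 / 4.0, rel=1e-6)
        assert vals["accel_mean_mm_s2"] == pytest.approx(0.0, abs=1e-6)
        assert vals["duration_s"] == pytest.approx(4.0)

    def test_too_few_samples_rejected(self):
        ex, spec = _make_drag_execution([(10, 10), (11, 11)])
        with pytest.raises(DataError):
            drag_features(ex, spec, _blank_windows(1)[0])


class TestUnifiedAssembly:
    def test_lengths_add_and_grip_propagates(self):
        def fv(scope, n):
            return FeatureVector(tuple(f"{scope}{i}" for i in range(n)),
                                 np.zeros(n), scope, grip_kg=30.0,
                                 participant_id="P01", day=1, set_index=1)
        u = assemble_unified(fv("tap", 3), fv("flick", 4), fv("drag", 5))
        assert len(u.names) == 12
        assert u.grip_kg == 30.0
        assert u.task_scope == "unified"

    def test_key_mismatch_rejected(self):
        a = FeatureVector(("x",), [0.0], "tap", 30.0, "P01", 1, 1)
        b = FeatureVector(("y",), [0.0], "flick", 30.0, "P01", 1, 2)
        c = FeatureVector(("z",), [0.0], "drag", 30.0, "P01", 1, 1)
        with pytest.raises(UsageError):
            assemble_unified(a, b, c)


class TestFeatureDictionary:
    def test_documents_every_feature_name(self, small_tables):
        from gripsense.features import feature_columns, feature_dictionary
        for scope, df in small_tables.items():
            names = feature_columns(df)
            d = feature_dictionary(names)
            assert set(d) == set(names)
            assert all("unit" in v and "definition" in v for v in d.values())


class TestEndToEndExtraction:
    def test_deterministic_and_finite(self, small_cohort):
        a = build_feature_table(small_cohort[:4], "unified")
        b = build_feature_table(small_cohort[:4], "unified")
        num_a = a.select_dtypes("number").to_numpy(float)
        np.testing.assert_array_equal(num_a,
                                      b.select_dtypes("number").to_numpy(float))
        assert np.all(np.isfinite(num_a))

    def test_translation_invariance_of_geometric_features(self, small_cohort):
        import dataclasses
        s = small_cohort[0]
        base = extract_set_features(s)
        shifted = dataclasses.replace(s)
        dx, dy = 2.0, -3.0
        new_exec = {}
        for task, ex in s.executions.items():
            ex2 = ex.copy()
            ex2.touch.x = ex2.touch.x + dx
            ex2.touch.y = ex2.touch.y + dy
            ex2.sub_events = [SubEvent(e.index, e.t_appear, e.t_input,
                                       e.target_x + dx, e.target_y + dy,
                                       e.success) for e in ex.sub_events]
            if ex2.spiral is not None:
                ex2.spiral = dataclasses.replace(
                    ex2.spiral, center_x=ex2.spiral.center_x + dx,
                    center_y=ex2.spiral.center_y + dy)
            new_exec[task] = ex2
        shifted = dataclasses.replace(s, executions=new_exec)
        moved = extract_set_features(shifted)
        for scope in ("tap", "flick", "drag"):
            va = dict(zip(base[scope].names, base[scope].values))
            vb = dict(zip(moved[scope].names, moved[scope].values))
            for name in va:
                if name.split("_")[0] in ("pre", "post", "during"):
                    continue  # sensor statistics are unaffected by touch shifts
                assert vb[name] == pytest.approx(va[name], abs=2e-3), name
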