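"""Signal primitives: smoothing, angles, quadrant encoding, rep detectors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinetracker.errors import (
    DegenerateGeometryError,
    InputError,
    ParameterError,
    UndefinedMetricError,
)
from kinetracker.kinematics import (
    FAIL,
    SUCCESS,
    CircularParams,
    RepEvent,
    circularity_metric,
    detect_circular_reps,
    detect_vertical_reps,
    moving_average,
    opening_angle,
    quadrant_sequence,
    segment_vertical_angle,
    smooth_stream,
)

from conftest import make_circle_traj


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def test_moving_average_hand_computed_example():
    y = np.array([0.0, 0.0, 3.0, 0.0, 0.0])
    assert np.allclose(moving_average(y, 3), [0.0, 1.0, 1.0, 1.0, 0.0])


def test_moving_average_identity_cases():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    assert np.array_equal(moving_average(y, 1), y)
    const = np.full(10, 2.5)
    assert np.allclose(moving_average(const, 5), const)


def test_moving_average_rejects_even_window():
    with pytest.raises(ParameterError):
        moving_average(np.zeros(5), 4)


def test_smooth_stream_commutes_with_rigid_translation():
    from kinetracker.synthetic import MotionSpec, generate_stream

    stream, _ = generate_stream(MotionSpec(exercise_id=1, reps_per_side=1))
    offset = [0.4, -1.1, 2.2]
    a = smooth_stream(stream.translated(offset), 5)
    b = smooth_stream(stream, 5).translated(offset)
    assert np.allclose(a.pos, b.pos)
    assert np.array_equal(a.t, stream.t)
    assert np.array_equal(a.tracked, stream.tracked)


# ---------------------------------------------------------------------------
# angles
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("a,b,c,expected", [
    ((0, 0, 0), (1, 0, 0), (2, 0, 0), 180.0),
    ((0, 1, 0), (0, 0, 0), (1, 0, 0), 90.0),
    ((0, 1, 0), (0, 0, 0), (1, 1, 0), 45.0),
])
def test_opening_angle_examples(a, b, c, expected):
    assert opening_angle(a, b, c) == pytest.approx(expected)


def test_opening_angle_degenerate():
    with pytest.raises(DegenerateGeometryError):
        opening_angle((1, 0, 0), (1, 0, 0), (2, 0, 0))


@given(st.tuples(*[st.floats(-5, 5) for _ in range(9)]))
@settings(max_examples=80, deadline=None)
def test_opening_angle_range_and_symmetry(coords):
    a, b, c = coords[:3], coords[3:6], coords[6:]
    if np.allclose(a, b) or np.allclose(c, b):
        return
    ang = opening_angle(a, b, c)
    assert 0.0 <= ang <= 180.0
    assert ang == pytest.approx(opening_angle(c, b, a))


@pytest.mark.parametrize("upper,lower,expected", [
    ((0, 1, 0), (0, 0, 0), 0.0),
    ((0, 0, 0), (1, 0, 0), 90.0),
    ((0, 1, 0), (1, 0, 0), 45.0),
])
def test_segment_vertical_angle_examples(upper, lower, expected):
    assert segment_vertical_angle(upper, lower) == pytest.approx(expected)


def test_segment_vertical_angle_coincident_points():
    with pytest.raises(DegenerateGeometryError):
        segment_vertical_angle((1, 1, 1), (1, 1, 1))


# ---------------------------------------------------------------------------
# quadrant encoding
# ---------------------------------------------------------------------------

def test_quadrant_sequence_full_circle_labels():
    # unit circle sampled at 90, 0, 270, 180, 90 degrees (v superior, u anterior)
    pts = [(0, 1), (1, 0), (0, -1), (-1, 0), (0, 1)]
    labels = quadrant_sequence(pts, (0.0, 0.0), 0.1)
    assert labels == ["superior", "anterior", "inferior", "posterior", "superior"]


def test_quadrant_sequence_deadband_swallows_small_motion():
    pts = [(0.01, 0.02), (-0.02, 0.01), (0.0, -0.02)]
    assert quadrant_sequence(pts, (0.0, 0.0), 0.1) == []


def test_quadrant_sequence_vertical_oscillation_never_lateral():
    t = np.linspace(0, 4 * np.pi, 200)
    pts = np.stack([np.zeros_like(t), 0.3 * np.sin(t)], axis=1)
    labels = quadrant_sequence(pts, (0.0, 0.0), 0.05)
    assert set(labels) == {"superior", "inferior"}


# ---------------------------------------------------------------------------
# circular repetition detection
# ---------------------------------------------------------------------------

def _successes(events):
    return [e for e in events if e.outcome == SUCCESS]


def _fails(events):
    return [e for e in events if e.outcome == FAIL]


def test_full_circles_all_counted_with_exact_extents():
    traj, t = make_circle_traj(cycles=10, points_per_cycle=96)
    events = detect_circular_reps(traj, t)
    succ = _successes(events)
    assert len(succ) == 10
    assert not _fails(events)
    for e in succ[1:]:  # steady-state events span exactly one full circle
        assert e.extent_superior_inferior == pytest.approx(0.30, abs=1e-9)
        assert e.extent_anterior_posterior == pytest.approx(0.30, abs=1e-9)


def test_half_circle_retrace_is_one_fail():
    traj, t = make_circle_traj(cycles=1, points_per_cycle=96, partial=0.5)
    events = detect_circular_reps(traj, t)
    assert len(_successes(events)) == 0
    assert len(_fails(events)) == 1


def test_small_arc_retrace_emits_nothing():
    # a quarter circle covers a single quadrant boundary: not half a circle
    traj, t = make_circle_traj(cycles=3, points_per_cycle=96, partial=0.25)
    assert detect_circular_reps(traj, t) == []


@pytest.mark.parametrize("axis", ["vertical", "horizontal", "diagonal"])
def test_linear_oscillation_rejected(axis):
    t = np.arange(300) / 30
    s = 0.15 * np.sin(2 * np.pi * t / 3)
    traj = {
        "vertical": np.stack([np.zeros_like(s), s], axis=1),
        "horizontal": np.stack([s, np.zeros_like(s)], axis=1),
        "diagonal": np.stack([s, s], axis=1),
    }[axis]
    assert detect_circular_reps(traj, t) == []


@pytest.mark.parametrize("cycles,ppc,partial", [
    (3, 60, None), (2, 90, None), (4, 40, None), (1, 100, None),
    (3, 60, 0.5), (2, 64, 0.75),
])
def test_success_count_matches_winding_number_oracle(cycles, ppc, partial):
    """Independent oracle: accumulated signed angle about the centroid."""
    traj, t = make_circle_traj(cycles, ppc, partial=partial)
    assert traj.shape[0] <= 210

    def winding_successes(tr):
        c = tr.mean(axis=0)
        ang = np.unwrap(np.arctan2(tr[:, 1] - c[1], tr[:, 0] - c[0]))
        acc, n = 0.0, 0
        for d in np.diff(ang):
            acc += d
            if abs(acc) >= 2 * np.pi:
                n += 1
                acc -= np.copysign(2 * np.pi, acc)
        return n

    detected = len(_successes(detect_circular_reps(traj, t)))
    assert detected == winding_successes(traj)


def test_time_reversal_preserves_success_count():
    traj, t = make_circle_traj(cycles=5, points_per_cycle=60)
    fwd = len(_successes(detect_circular_reps(traj, t)))
    rev = len(_successes(detect_circular_reps(traj[::-1].copy(), t)))
    assert fwd == rev == 5


def test_reflection_preserves_success_count():
    traj, t = make_circle_traj(cycles=5, points_per_cycle=60)
    mirrored = traj * np.array([-1.0, 1.0])
    assert len(_successes(detect_circular_reps(mirrored, t))) == 5


def test_ellipse_circularity_is_axis_ratio():
    traj, t = make_circle_traj(cycles=6, points_per_cycle=96,
                               radius_v=0.2, radius_u=0.1)
    events = _successes(detect_circular_reps(traj, t))
    # steady-state events span exactly one full cycle; the first event starts
    # mid-motion and may clip an extreme, so it is excluded from the exact check
    assert circularity_metric(events[1:]) == pytest.approx(2.0, rel=1e-9)
    assert circularity_metric(events) == pytest.approx(2.0, rel=0.02)


def test_circularity_of_circles_is_one_for_any_radius():
    for r in (0.05, 0.15, 0.4):
        traj, t = make_circle_traj(cycles=4, points_per_cycle=96,
                                   radius_v=r, radius_u=r)
        events = _successes(detect_circular_reps(traj, t))
        assert circularity_metric(events[1:]) == pytest.approx(1.0, abs=1e-9)
        assert circularity_metric(events) == pytest.approx(1.0, abs=0.02)


def test_circularity_metric_edge_cases():
    e = RepEvent(outcome=SUCCESS, t_start=0, t_end=1,
                 extent_superior_inferior=0.3, extent_anterior_posterior=0.3)
    assert circularity_metric([e]) == 1.0
    with pytest.raises(UndefinedMetricError):
        circularity_metric([])
    flat = RepEvent(outcome=SUCCESS, t_start=0, t_end=1,
                    extent_superior_inferior=0.3, extent_anterior_posterior=0.0)
    with pytest.raises(UndefinedMetricError):
        circularity_metric([flat])


def test_circular_detector_empty_input():
    assert detect_circular_reps(np.empty((0, 2)), np.empty(0)) == []


# ---------------------------------------------------------------------------
# vertical repetition detection
# ---------------------------------------------------------------------------

def _triangle_signal(depths, points_per_cycle=60, fps=30.0, direction="down"):
    """Triangle-wave excursions from baseline 1.0; peak sampled exactly."""
    sign = -1.0 if direction == "down" else 1.0
    parts = [np.full(10, 1.0)]
    for d in depths:
        half = points_per_cycle // 2
        up = np.linspace(0.0, 1.0, half, endpoint=True)
        cyc = np.concatenate([up, up[::-1][1:]])
        parts.append(1.0 + sign * d * cyc)
        parts.append(np.full(5, 1.0))
    sig = np.concatenate(parts)
    t = np.arange(sig.size) / fps
    return t, sig


def test_deep_dips_are_successes_with_exact_travel():
    thr = 0.15
    t, sig = _triangle_signal([1.2 * thr] * 10)
    events = detect_vertical_reps(t, sig, baseline=1.0, threshold=thr)
    assert len(events) == 10
    assert all(e.outcome == SUCCESS for e in events)
    for e in events:
        assert e.vertical_travel == pytest.approx(1.2 * thr)


def test_shallow_dips_are_fails():
    thr = 0.15
    t, sig = _triangle_signal([0.5 * thr] * 5)
    events = detect_vertical_reps(t, sig, baseline=1.0, threshold=thr)
    assert len(events) == 5
    assert all(e.outcome == FAIL for e in events)


def test_sub_floor_wiggles_emit_nothing():
    # excursions above hysteresis but below the attempt floor
    t, sig = _triangle_signal([0.03] * 4)
    events = detect_vertical_reps(t, sig, baseline=1.0, threshold=0.15,
                                  hysteresis=0.02, attempt_floor=2.0)
    assert events == []


def test_flat_signal_no_events():
    t = np.arange(100) / 30
    assert detect_vertical_reps(t, np.ones(100), 1.0, 0.15) == []


def test_upward_direction_detects_lifts():
    t, sig = _triangle_signal([0.3] * 3, direction="up")
    events = detect_vertical_reps(t, sig, baseline=1.0, threshold=0.2,
                                  direction="up")
    assert [e.outcome for e in events] == [SUCCESS] * 3


def test_success_partition_monotone_in_threshold():
    depths = [0.05, 0.1, 0.18, 0.25, 0.3]
    t, sig = _triangle_signal(depths)
    prev_successes = None
    for thr in (0.08, 0.15, 0.22, 0.35):
        events = detect_vertical_reps(t, sig, 1.0, thr)
        n_succ = sum(e.outcome == SUCCESS for e in events)
        if prev_successes is not None:
            assert n_succ <= prev_successes  # raising threshold never helps
        prev_successes = n_succ


def test_inclusive_flag_controls_boundary_comparison():
    # depth 0.25 is exactly representable, so travel == threshold exactly
    t, sig = _triangle_signal([0.25])
    strict = detect_vertical_reps(t, sig, 1.0, threshold=0.25)
    incl = detect_vertical_reps(t, sig, 1.0, threshold=0.25, inclusive=True)
    assert strict[0].outcome == FAIL
    assert incl[0].outcome == SUCCESS


def test_vertical_detector_rejects_nonmonotone_time():
    with pytest.raises(InputError):
        detect_vertical_reps(np.array([0.0, 0.1, 0.1]), np.zeros(3), 1.0, 0.1)
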