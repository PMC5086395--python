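"""Exercise engines: thresholds, counters, demotions, metrics, symmetries."""

import numpy as np
import pytest

from kinetracker import (
    BodyMetrics,
    ExerciseConfig,
    generate_stream,
    mirror_lr,
    resolve_defaults,
    run_exercise,
)
from kinetracker.errors import InputError
from kinetracker.exercises import EXERCISES
from kinetracker.skeleton import JOINT_INDEX
from kinetracker.synthetic import MotionSpec, SideMotion

TEMPLATE_BODY = BodyMetrics(L_Thigh=0.45, R_Thigh=0.45, L_Shin=0.40, R_Shin=0.40,
                            L_Arm=0.30, R_Arm=0.30)


def _run(ex, config=None, **spec_kw):
    spec = MotionSpec(exercise_id=ex, **spec_kw)
    stream, truth = generate_stream(spec)
    config = config or ExerciseConfig(exercise_id=ex)
    return run_exercise(stream, config), truth.expected(config)


# ---------------------------------------------------------------------------
# defaults
# ---------------------------------------------------------------------------

def test_default_squat_threshold_is_sixth_of_summed_thighs():
    cfg = resolve_defaults(ExerciseConfig(exercise_id=2), TEMPLATE_BODY)
    assert cfg.D_min == pytest.approx((0.45 + 0.45) / 6)
    assert cfg.D_min == pytest.approx(0.15)


def test_default_kick_threshold_is_three_quarters_of_mean_shin():
    cfg = resolve_defaults(ExerciseConfig(exercise_id=5), TEMPLATE_BODY)
    assert cfg.H_min == pytest.approx(0.75 * (0.40 + 0.40) / 2)
    assert cfg.H_min == pytest.approx(0.30)


def test_explicit_thresholds_pass_through():
    cfg = resolve_defaults(ExerciseConfig(exercise_id=2, D_min=0.10), TEMPLATE_BODY)
    assert cfg.D_min == 0.10


def test_exactly_five_engines_exposed():
    assert sorted(EXERCISES) == [1, 2, 3, 4, 5]
    assert all(callable(f) for f in EXERCISES.values())


def test_engine_rejects_mismatched_exercise_id():
    stream, _ = generate_stream(MotionSpec(exercise_id=1, reps_per_side=1))
    with pytest.raises(InputError):
        EXERCISES[2](stream, ExerciseConfig(exercise_id=1))


# ---------------------------------------------------------------------------
# ground-truth recovery per engine
# ---------------------------------------------------------------------------

def _assert_counters(result, expected):
    assert result.counters.to_dict() == expected["counters"].to_dict()
    assert result.complete == expected["complete"]


def _assert_metrics(result, expected, rel=0.01):
    for k, want in expected["metrics"].items():
        got = result.metrics[k]
        if want is None:
            assert got is None, k
        else:
            assert got == pytest.approx(want, rel=rel), k


@pytest.mark.parametrize("ex", [1, 2, 3, 4, 5])
def test_perfect_execution_recovers_ground_truth(ex, perfect_runs):
    _, truth, result = perfect_runs[ex]
    expected = truth.expected()
    _assert_counters(result, expected)
    _assert_metrics(result, expected)
    assert result.complete


def test_vertical_ellipse_right_wrist_doubles_circularity():
    result, expected = _run(1, right=SideMotion(radius_v=0.2, radius_u=0.1))
    _assert_counters(result, expected)
    assert result.metrics["circularity_R"] == pytest.approx(2.0, rel=0.01)
    assert result.metrics["circularity_L"] == pytest.approx(1.0, rel=0.01)


def test_bent_arm_demotes_completed_circles():
    result, expected = _run(1, right=SideMotion(arm_bend_deg=120))
    _assert_counters(result, expected)
    assert result.counters.R_s == 0
    assert result.counters.R_f == 10
    assert result.counters.L_s == 10
    assert any(w["type"] == "demotion" for w in result.warnings)


def test_partial_circles_all_fail():
    result, expected = _run(1, left=SideMotion(partial_fraction=0.5),
                            right=SideMotion(partial_fraction=0.5))
    _assert_counters(result, expected)
    assert result.counters.L_s == 0 and result.counters.R_s == 0
    assert result.counters.L_f > 0


def test_alternating_squat_depths_counts_fails_and_averages_successes_only():
    depths = [0.18, 0.075] * 10  # deep, shallow, ... until 10 successes
    result, expected = _run(2, depth_sequence=depths)
    _assert_counters(result, expected)
    assert result.counters.M_s == 10
    assert result.counters.M_f == 9  # the 20th squat falls after the freeze
    assert result.metrics["mean_depth_pct"] == pytest.approx(120.0, rel=0.01)


def test_no_movement_yields_no_squats():
    result, expected = _run(2, depth_sequence=[0.18], reps_per_side=1,
                            config=ExerciseConfig(exercise_id=2, D_min=0.5))
    # single too-shallow squat against a high threshold: one fail, incomplete
    assert result.counters.M_s == 0
    assert not result.complete


def test_tilted_forearm_fails_that_side_only():
    result, expected = _run(3, right=SideMotion(forearm_tilt_deg=40))
    _assert_counters(result, expected)
    assert result.counters.L_s == 10 and result.counters.R_s == 0
    assert result.counters.R_f == 10


def test_low_lift_travel_fails():
    result, expected = _run(3, left=SideMotion(lift_fraction=0.5),
                            right=SideMotion(lift_fraction=0.5))
    _assert_counters(result, expected)
    assert result.counters.L_s == 0 and result.counters.L_f == 10


def test_lift_metrics_report_travel_as_percent_of_arm():
    result, expected = _run(3)
    assert result.metrics["mean_height_pct_L"] == pytest.approx(75.0, rel=0.01)
    assert result.metrics["mean_height_pct_R"] == pytest.approx(75.0, rel=0.01)


def test_stick_circles_out_of_phase_demote_both_sides():
    result, expected = _run(4, phase_lag=0.5)
    _assert_counters(result, expected)
    assert result.counters.L_s == 0 and result.counters.R_s == 0
    assert result.counters.L_f == 10 and result.counters.R_f == 10


def test_stick_circles_in_phase_identical_to_exercise1_metrics():
    result, expected = _run(4)
    _assert_counters(result, expected)
    assert set(result.metrics) == {"L_f", "R_f", "circularity_L", "circularity_R"}
    assert result.metrics["circularity_L"] == pytest.approx(1.0, rel=0.01)


def test_leg_kicks_order_free():
    alt, exp_alt = _run(5)
    blocked, exp_blk = _run(5, leg_order=["L"] * 10 + ["R"] * 10)
    _assert_counters(alt, exp_alt)
    _assert_counters(blocked, exp_blk)
    assert alt.counters.to_dict() == blocked.counters.to_dict()


def test_shallow_right_kicks_fail():
    # 0.6 * shin = 0.8 * H_min for the template body
    result, expected = _run(5, right=SideMotion(kick_fraction=0.6))
    _assert_counters(result, expected)
    assert result.counters.R_s == 0 and result.counters.R_f == 10
    assert result.counters.L_s == 10


# ---------------------------------------------------------------------------
# counter semantics and symmetries
# ---------------------------------------------------------------------------

def test_counters_freeze_once_target_reached():
    base, _ = _run(2, reps_per_side=10)
    extra, _ = _run(2, reps_per_side=13)  # three repetitions beyond the target
    assert base.counters.to_dict() == extra.counters.to_dict()
    assert extra.counters.M_s == 10


def test_failure_counter_freezes_with_success_counter():
    depths = [0.18] * 10 + [0.075] * 3  # shallow squats after completion
    result, expected = _run(2, depth_sequence=depths)
    _assert_counters(result, expected)
    assert result.counters.M_f == 0


def test_metric_averages_ignore_failed_repetitions():
    clean, _ = _run(2, depth_sequence=[0.18] * 10)
    noisy, _ = _run(2, depth_sequence=[0.18, 0.075] * 10)
    assert noisy.metrics["mean_depth_pct"] == pytest.approx(
        clean.metrics["mean_depth_pct"], rel=1e-6)


@pytest.mark.parametrize("ex", [1, 3, 5])
def test_mirror_equivalence_swaps_sides_exactly(ex):
    kw = {
        1: dict(right=SideMotion(arm_bend_deg=120)),
        3: dict(right=SideMotion(forearm_tilt_deg=40)),
        5: dict(right=SideMotion(kick_fraction=0.6)),
    }[ex]
    spec = MotionSpec(exercise_id=ex, reps_per_side=4, **kw)
    stream, _ = generate_stream(spec)
    cfg = ExerciseConfig(exercise_id=ex)
    straight = run_exercise(stream, cfg)
    mirrored = run_exercise(mirror_lr(stream), cfg)
    c1, c2 = straight.counters, mirrored.counters
    assert (c1.L_s, c1.L_f) == (c2.R_s, c2.R_f)
    assert (c1.R_s, c1.R_f) == (c2.L_s, c2.L_f)


def test_long_inferred_run_pauses_that_side():
    spec = MotionSpec(exercise_id=1, reps_per_side=5)
    stream, _ = generate_stream(spec)
    # hide the left wrist for one whole repetition block (96 frames + rests)
    a = int(round((1.0 + 2 * (3.2 + 0.5)) * 30)) - 8
    b = a + int(round(3.2 * 30)) + 16
    stream.tracked[a:b, JOINT_INDEX["WristL"]] = False
    result = run_exercise(stream, ExerciseConfig(exercise_id=1))
    assert any(w["type"] == "tracking_pause" for w in result.warnings)
    assert result.counters.L_s == 4  # the occluded repetition is not counted
    assert result.counters.R_s == 5


def test_short_inferred_runs_are_tolerated():
    spec = MotionSpec(exercise_id=1, reps_per_side=3)
    stream, truth = generate_stream(spec)
    stream.tracked[40:50, JOINT_INDEX["WristL"]] = False  # 10 frames < limit
    result = run_exercise(stream, ExerciseConfig(exercise_id=1))
    assert result.counters.L_s == 3
    assert not any(w["type"] == "tracking_pause" for w in result.warnings)
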