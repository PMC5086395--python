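"""The five exercise engines: checks, counters, completion and metrics.

Each engine consumes a :class:`~kinetracker.skeleton.SkeletonStream` and an
:class:`ExerciseConfig` and produces a :class:`SessionResult`:

1. **Arm circles** (standing, arms extended laterally): each wrist must trace
   circles in a plane parallel to the sagittal plane while the
   shoulder-elbow-wrist opening angle stays near 180 degrees.
2. **Squats**: the mid-hip joint must travel down by more than ``D_min``.
3. **Elbow lifts**: both upper arms rise toward horizontal; each elbow must
   travel up by a per-arm fraction of the upper-arm length while the forearm
   stays close to vertical.
4. **Broomstick circles** (seated): as exercise 1 without the extension check,
   but the two wrists must move in unison (quadrant transitions in phase).
5. **Leg kicks** (seated): each ankle must rise above ``H_min``, legs in any
   order.

Counters follow the on-screen semantics: per-side success counters freeze at
the target ``N`` (and with them that side's failure counter); the exercise is
complete when every relevant success counter equals ``N``.  The ``<.>``
averages in the end-of-exercise metrics run over counted successful
repetitions only.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field as dc_field
from typing import Literal, Optional, Union

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .errors import ConfigError, InputError
from .kinematics import (
    FAIL,
    SUCCESS,
    CircularParams,
    RepEvent,
    Transition,
    circular_rep_analysis,
    detect_vertical_reps,
    opening_angles,
    segment_vertical_angles,
    smooth_stream,
)
from .skeleton import (
    BodyMetrics,
    SkeletonStream,
    calibration_slice,
    estimate_body_metrics,
    project_points,
)

#: consecutive inferred frames of a required joint tolerated before the engine
#: pauses (no events emitted until tracking resumes)
MAX_INFERRED_RUN = 15

AUTO = "auto"


class ExerciseConfig(BaseModel):
    """Serializable configuration of one exercise session.

    Thresholds may be given explicitly in meters or left ``"auto"`` to be
    resolved from the patient's body proportions: ``D_min`` (minimum squat
    depth) defaults to ``(L_Thigh + R_Thigh) / 6`` and ``H_min`` (minimum
    ankle lift) to ``0.75 * (L_Shin + R_Shin) / 2``, both average difficulty.
    The elbow-lift height targets are per-arm ratios of the arm length
    (0.7 poses realistic expectations for most patients; 1.0 is full range).
    """

    exercise_id: int = Field(ge=1, le=5)
    N: int = Field(default=10, ge=1)
    D_min: Union[Literal["auto"], float] = AUTO
    H_min: Union[Literal["auto"], float] = AUTO
    height_ratio_L: float = Field(default=0.7, gt=0, le=1.5)
    height_ratio_R: float = Field(default=0.7, gt=0, le=1.5)
    arm_extension_min_angle: float = Field(default=160.0, gt=0, le=180)
    forearm_vertical_tol: float = Field(default=20.0, gt=0, le=180)
    unison_lag_tol: float = Field(default=0.25, ge=0)
    deadband: float = Field(default=0.03, ge=0)
    hysteresis: float = Field(default=0.02, ge=0)
    attempt_floor: float = Field(default=2.0, ge=0)
    smoothing_window: int = Field(default=5, ge=1)
    max_rep_duration: float = Field(default=10.0, gt=0)
    center_window: float = Field(default=2.0, gt=0)
    calibration_window: float = Field(default=1.0, gt=0)
    arm_segment: Literal["upper", "fore"] = "upper"

    @field_validator("smoothing_window")
    @classmethod
    def _odd(cls, v: int) -> int:
        if v % 2 == 0:
            raise ValueError("smoothing_window must be odd")
        return v

    @field_validator("D_min", "H_min")
    @classmethod
    def _positive_or_auto(cls, v):
        if v != AUTO and v <= 0:
            raise ValueError("explicit thresholds must be positive")
        return v

    def circular_params(self) -> CircularParams:
        return CircularParams(deadband=self.deadband,
                              max_rep_duration=self.max_rep_duration,
                              center_window=self.center_window)


def resolve_defaults(config: ExerciseConfig, body: BodyMetrics) -> ExerciseConfig:
    """Resolve ``auto`` thresholds against the patient's body proportions."""
    updates: dict = {}
    if config.D_min == AUTO:
        updates["D_min"] = (body.L_Thigh + body.R_Thigh) / 6.0
    if config.H_min == AUTO:
        updates["H_min"] = 0.75 * (body.L_Shin + body.R_Shin) / 2.0
    resolved = config.model_copy(update=updates)
    for name in ("D_min", "H_min"):
        v = getattr(resolved, name)
        if not (isinstance(v, (int, float)) and v > 0):
            raise ConfigError(f"{name} resolved to non-positive value {v!r}")
    return resolved


@dataclass
class Counters:
    """On-screen repetition counters; ``M_*`` are used by the squat exercise."""

    L_s: int = 0
    R_s: int = 0
    L_f: int = 0
    R_f: int = 0
    M_s: int = 0
    M_f: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("L_s", "R_s", "L_f", "R_f", "M_s", "M_f")}


@dataclass
class SessionResult:
    """Outcome of running one exercise engine over a recorded stream."""

    exercise_id: int
    config: dict
    body: dict
    counters: Counters
    events: list[RepEvent]
    complete: bool
    metrics: dict
    warnings: list[dict] = dc_field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "exercise_id": self.exercise_id,
            "config": self.config,
            "body": self.body,
            "counters": self.counters.to_dict(),
            "events": [e.to_dict() for e in self.events],
            "complete": self.complete,
            "metrics": self.metrics,
            "warnings": self.warnings,
        }


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------

def _prepare(stream: SkeletonStream, config: ExerciseConfig):
    body = estimate_body_metrics(stream, config.calibration_window, config.arm_segment)
    cfg = resolve_defaults(config, body)
    sm = smooth_stream(stream, cfg.smoothing_window)
    return body, cfg, sm


def _baseline(sm: SkeletonStream, joint: str, cfg: ExerciseConfig) -> float:
    sl = calibration_slice(sm, cfg.calibration_window)
    return float(np.median(sm.joint(joint)[sl, 1]))


def _valid_segments(sm: SkeletonStream, joints: list[str]) -> tuple[list[slice], list[dict]]:
    """Split the stream at runs of > MAX_INFERRED_RUN consecutive inferred frames.

    Short inferred runs are used as-is (the sensor SDK estimates those
    positions from tracked joints); long runs pause the engine.
    """
    ok = np.ones(len(sm), dtype=bool)
    for j in joints:
        ok &= sm.joint_tracked(j)
    segments: list[slice] = []
    warnings: list[dict] = []
    n = len(sm)
    i = 0
    seg_start = 0
    while i < n:
        if ok[i]:
            i += 1
            continue
        j = i
        while j < n and not ok[j]:
            j += 1
        if j - i > MAX_INFERRED_RUN:
            if i > seg_start:
                segments.append(slice(seg_start, i))
            warnings.append({"type": "tracking_pause",
                             "t_start": float(sm.t[i]), "t_end": float(sm.t[j - 1]),
                             "frames": int(j - i)})
            seg_start = j
        i = j
    if n > seg_start:
        segments.append(slice(seg_start, n))
    return segments, warnings


def _circular_side(sm: SkeletonStream, cfg: ExerciseConfig, side: str,
                   extra_joints: tuple[str, ...] = ()):
    """Detect circular wrist repetitions for one side; returns events + transitions."""
    joints = [f"Shoulder{side}", f"Elbow{side}", f"Wrist{side}", *extra_joints]
    traj = project_points(sm.joint(f"Wrist{side}"), "sagittal")
    segments, warnings = _valid_segments(sm, joints)
    events: list[RepEvent] = []
    transitions: list[Transition] = []
    for seg in segments:
        ev, tr = circular_rep_analysis(traj[seg], sm.t[seg], cfg.circular_params())
        events.extend(ev)
        transitions.extend(tr)
    for k, e in enumerate(events, start=1):
        e.side, e.index = side, k
    return events, transitions, warnings


def _count_side(events: list[RepEvent], N: int) -> tuple[int, int, list[RepEvent]]:
    """Apply counter semantics: freeze both counters once successes reach N."""
    s = f = 0
    counted_successes: list[RepEvent] = []
    for e in sorted(events, key=lambda e: e.t_end):
        if s >= N:
            break
        if e.outcome == SUCCESS:
            s += 1
            counted_successes.append(e)
        else:
            f += 1
    return s, f, counted_successes


def _circularity(successes: list[RepEvent]) -> Optional[float]:
    if not successes:
        return None
    si = float(np.mean([e.extent_superior_inferior for e in successes]))
    ap = float(np.mean([e.extent_anterior_posterior for e in successes]))
    return si / ap if ap > 0 else None


def _frame_range(sm: SkeletonStream, e: RepEvent) -> slice:
    i0 = int(np.searchsorted(sm.t, e.t_start, side="left"))
    i1 = int(np.searchsorted(sm.t, e.t_end, side="right"))
    return slice(i0, max(i1, i0 + 1))


def _demote(e: RepEvent, reason: str, warnings: list[dict]) -> None:
    e.outcome = FAIL
    warnings.append({"type": "demotion", "side": e.side, "index": e.index,
                     "t_start": e.t_start, "t_end": e.t_end, "reason": reason})


def _result(exercise_id, config, body, counters, events, complete, metrics, warnings):
    return SessionResult(
        exercise_id=exercise_id,
        config=config.model_dump(),
        body={k: getattr(body, k) for k in
              ("L_Thigh", "R_Thigh", "L_Shin", "R_Shin", "L_Arm", "R_Arm")},
        counters=counters,
        events=sorted(events, key=lambda e: (e.t_end, e.side or "")),
        complete=complete,
        metrics=metrics,
        warnings=warnings,
    )


def _require(config: ExerciseConfig, exercise_id: int) -> None:
    if config.exercise_id != exercise_id:
        raise InputError(f"config.exercise_id is {config.exercise_id}, engine expects {exercise_id}")


# ---------------------------------------------------------------------------
# engines
# ---------------------------------------------------------------------------

def run_exercise1(stream: SkeletonStream, config: ExerciseConfig) -> SessionResult:
    """Arm circles with laterally extended arms.

    A detector success is demoted to a fail when the arm's shoulder-elbow-wrist
    opening angle fell below ``arm_extension_min_angle`` at any frame of the
    repetition (effort is still acknowledged in the failure counter).
    """
    _require(config, 1)
    body, cfg, sm = _prepare(stream, config)
    counters = Counters()
    all_events: list[RepEvent] = []
    warnings: list[dict] = []
    metrics: dict = {}
    for side in ("L", "R"):
        events, _, w = _circular_side(sm, cfg, side)
        warnings.extend(w)
        angles = opening_angles(sm.joint(f"Shoulder{side}"), sm.joint(f"Elbow{side}"),
                                sm.joint(f"Wrist{side}"))
        for e in events:
            if e.outcome == SUCCESS and float(np.min(angles[_frame_range(sm, e)])) \
                    < cfg.arm_extension_min_angle:
                _demote(e, "arm not fully extended", warnings)
        s, f, successes = _count_side(events, cfg.N)
        setattr(counters, f"{side}_s", s)
        setattr(counters, f"{side}_f", f)
        metrics[f"{side}_f"] = f
        metrics[f"circularity_{side}"] = _circularity(successes)
        all_events.extend(events)
    complete = counters.L_s == cfg.N and counters.R_s == cfg.N
    return _result(1, cfg, body, counters, all_events, complete, metrics, warnings)


def run_exercise2(stream: SkeletonStream, config: ExerciseConfig) -> SessionResult:
    """Squats: mid-hip vertical travel against the standing baseline."""
    _require(config, 2)
    body, cfg, sm = _prepare(stream, config)
    segments, warnings = _valid_segments(sm, ["HipCenter"])
    baseline = _baseline(sm, "HipCenter", cfg)
    y = sm.joint("HipCenter")[:, 1]
    events: list[RepEvent] = []
    for seg in segments:
        events.extend(detect_vertical_reps(
            sm.t[seg], y[seg], baseline, threshold=float(cfg.D_min), direction="down",
            hysteresis=cfg.hysteresis, max_rep_duration=cfg.max_rep_duration,
            attempt_floor=cfg.attempt_floor))
    for k, e in enumerate(events, start=1):
        e.side, e.index = "mid", k
    s, f, successes = _count_side(events, cfg.N)
    counters = Counters(M_s=s, M_f=f)
    mean_depth = float(np.mean([e.vertical_travel for e in successes])) if successes else None
    metrics = {
        "M_f": f,
        "mean_depth_pct": None if mean_depth is None else 100.0 * mean_depth / float(cfg.D_min),
    }
    complete = counters.M_s == cfg.N
    return _result(2, cfg, body, counters, events, complete, metrics, warnings)


def run_exercise3(stream: SkeletonStream, config: ExerciseConfig) -> SessionResult:
    """Elbow lifts: per-arm elbow rise with the forearm held near vertical.

    Success requires the elbow's vertical travel to reach the per-arm target
    ``height_ratio * arm length`` (inclusive, per the exercise's "close to"
    phrasing) and the forearm to stay within ``forearm_vertical_tol`` of
    vertical at every frame of the repetition.
    """
    _require(config, 3)
    body, cfg, sm = _prepare(stream, config)
    counters = Counters()
    all_events: list[RepEvent] = []
    warnings: list[dict] = []
    metrics: dict = {}
    for side in ("L", "R"):
        arm_len = body.segment(f"{side}_Arm")
        target = getattr(cfg, f"height_ratio_{side}") * arm_len
        joints = [f"Elbow{side}", f"Wrist{side}"]
        segments, w = _valid_segments(sm, joints)
        warnings.extend(w)
        baseline = _baseline(sm, f"Elbow{side}", cfg)
        y = sm.joint(f"Elbow{side}")[:, 1]
        tilt = segment_vertical_angles(sm.joint(f"Elbow{side}"), sm.joint(f"Wrist{side}"))
        events: list[RepEvent] = []
        for seg in segments:
            events.extend(detect_vertical_reps(
                sm.t[seg], y[seg], baseline, threshold=target, direction="up",
                hysteresis=cfg.hysteresis, max_rep_duration=cfg.max_rep_duration,
                attempt_floor=cfg.attempt_floor, inclusive=True))
        for k, e in enumerate(events, start=1):
            e.side, e.index = side, k
            if e.outcome == SUCCESS and float(np.max(tilt[_frame_range(sm, e)])) \
                    > cfg.forearm_vertical_tol:
                _demote(e, "forearm not vertical", warnings)
        s, f, successes = _count_side(events, cfg.N)
        setattr(counters, f"{side}_s", s)
        setattr(counters, f"{side}_f", f)
        mean_h = float(np.mean([e.vertical_travel for e in successes])) if successes else None
        metrics[f"{side}_f"] = f
        metrics[f"mean_height_pct_{side}"] = None if mean_h is None else 100.0 * mean_h / arm_len
        all_events.extend(events)
    complete = counters.L_s == cfg.N and counters.R_s == cfg.N
    return _result(3, cfg, body, counters, all_events, complete, metrics, warnings)


def run_exercise4(stream: SkeletonStream, config: ExerciseConfig) -> SessionResult:
    """Broomstick circles: as exercise 1 without the extension check, plus unison.

    A repetition on one wrist is demoted to a fail when any of its quadrant
    transitions has no matching transition (same quadrant crossing) on the
    other wrist within ``unison_lag_tol`` seconds.
    """
    _require(config, 4)
    body, cfg, sm = _prepare(stream, config)
    per_side: dict[str, tuple[list[RepEvent], list[Transition]]] = {}
    warnings: list[dict] = []
    for side in ("L", "R"):
        events, transitions, w = _circular_side(sm, cfg, side)
        warnings.extend(w)
        per_side[side] = (events, transitions)

    # index transitions by quadrant crossing for the unison check
    trans_index: dict[str, dict[tuple[str, str], list[float]]] = {}
    for side, (_, transitions) in per_side.items():
        d: dict[tuple[str, str], list[float]] = {}
        for tr in transitions:
            d.setdefault((tr.from_, tr.to), []).append(tr.t)
        trans_index[side] = d

    def in_unison(side: str, e: RepEvent) -> bool:
        other = trans_index["R" if side == "L" else "L"]
        for tr in per_side[side][1]:
            if not (e.t_start <= tr.t <= e.t_end):
                continue
            times = other.get((tr.from_, tr.to), [])
            if not times:
                return False
            i = bisect.bisect_left(times, tr.t)
            best = min(
                (abs(times[j] - tr.t) for j in (i - 1, i) if 0 <= j < len(times)),
                default=np.inf,
            )
            if best > cfg.unison_lag_tol:
                return False
        return True

    counters = Counters()
    all_events: list[RepEvent] = []
    metrics: dict = {}
    for side in ("L", "R"):
        events, _ = per_side[side]
        for e in events:
            if e.outcome == SUCCESS and not in_unison(side, e):
                _demote(e, "wrists not in unison", warnings)
        s, f, successes = _count_side(events, cfg.N)
        setattr(counters, f"{side}_s", s)
        setattr(counters, f"{side}_f", f)
        metrics[f"{side}_f"] = f
        metrics[f"circularity_{side}"] = _circularity(successes)
        all_events.extend(events)
    complete = counters.L_s == cfg.N and counters.R_s == cfg.N
    return _result(4, cfg, body, counters, all_events, complete, metrics, warnings)


def run_exercise5(stream: SkeletonStream, config: ExerciseConfig) -> SessionResult:
    """Seated leg kicks: per-leg ankle rise above ``H_min``, legs in any order."""
    _require(config, 5)
    body, cfg, sm = _prepare(stream, config)
    counters = Counters()
    all_events: list[RepEvent] = []
    warnings: list[dict] = []
    metrics: dict = {}
    for side in ("L", "R"):
        segments, w = _valid_segments(sm, [f"Ankle{side}"])
        warnings.extend(w)
        baseline = _baseline(sm, f"Ankle{side}", cfg)
        y = sm.joint(f"Ankle{side}")[:, 1]
        events: list[RepEvent] = []
        for seg in segments:
            events.extend(detect_vertical_reps(
                sm.t[seg], y[seg], baseline, threshold=float(cfg.H_min), direction="up",
                hysteresis=cfg.hysteresis, max_rep_duration=cfg.max_rep_duration,
                attempt_floor=cfg.attempt_floor))
        for k, e in enumerate(events, start=1):
            e.side, e.index = side, k
        s, f, successes = _count_side(events, cfg.N)
        setattr(counters, f"{side}_s", s)
        setattr(counters, f"{side}_f", f)
        shin = body.segment(f"{side}_Shin")
        mean_h = float(np.mean([e.vertical_travel for e in successes])) if successes else None
        metrics[f"{side}_f"] = f
        metrics[f"mean_height_pct_{side}"] = None if mean_h is None else 100.0 * mean_h / shin
        all_events.extend(events)
    complete = counters.L_s == cfg.N and counters.R_s == cfg.N
    return _result(5, cfg, body, counters, all_events, complete, metrics, warnings)


#: the exercise menu: id -> engine
EXERCISES = {
    1: run_exercise1,
    2: run_exercise2,
    3: run_exercise3,
    4: run_exercise4,
    5: run_exercise5,
}


def run_exercise(stream: SkeletonStream, config: ExerciseConfig) -> SessionResult:
    """Dispatch to the engine selected by ``config.exercise_id``."""
    return EXERCISES[config.exercise_id](stream, config)
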