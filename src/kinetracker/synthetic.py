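"""Sensor-free generator of skeleton streams with known ground truth.

The generator emulates the five exercise movement patterns on a template
body, producing kinematically consistent streams (constant segment lengths,
wrist circles in planes parallel to the sagittal plane, squats that bend the
knees, lifts that rotate the upper arm) together with the analytic ground
truth of every repetition.  It replaces the depth sensor for all testing: a
noiseless stream run through the exercise engines must recover the ground
truth; :func:`corrupt_stream` then layers on the imperfections of real
hardware (positional jitter, resting tremor, occasional inferred joints).

All motion profiles are sampled on exact frame boundaries: movement blocks
span a whole number of frames and amplitude peaks fall on sampled frames, so
the analytic amplitudes are attained by the discrete signal, not just its
continuous limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field

from .errors import MotionSpecError
from .exercises import ExerciseConfig, Counters, resolve_defaults
from .kinematics import SUCCESS, FAIL
from .skeleton import (
    BodyMetrics,
    JOINT_INDEX,
    N_JOINTS,
    SkeletonStream,
)


class BodyTemplate(BaseModel):
    """Segment lengths (meters) of the simulated subject."""

    thigh: float = Field(default=0.45, gt=0)
    shin: float = Field(default=0.40, gt=0)
    upper_arm: float = Field(default=0.30, gt=0)
    forearm: float = Field(default=0.27, gt=0)

    def body_metrics(self, arm_segment: str = "upper") -> BodyMetrics:
        arm = self.upper_arm if arm_segment == "upper" else self.forearm
        return BodyMetrics(L_Thigh=self.thigh, R_Thigh=self.thigh,
                           L_Shin=self.shin, R_Shin=self.shin,
                           L_Arm=arm, R_Arm=arm)


class SideMotion(BaseModel):
    """Per-side movement parameters.

    ``partial_fraction`` is the fraction of a circle traced before retracing
    (1.0 = full circles).  ``amplitude_sequence`` optionally overrides the
    lift/kick fraction repetition by repetition.
    """

    radius_u: float = Field(default=0.15, gt=0)      # anterior semi-axis (m)
    radius_v: float = Field(default=0.15, gt=0)      # superior semi-axis (m)
    partial_fraction: float = Field(default=1.0, gt=0, le=1.0)
    arm_bend_deg: float = Field(default=180.0, gt=0, le=180.0)
    forearm_tilt_deg: float = Field(default=0.0, ge=0, lt=90.0)
    lift_fraction: float = Field(default=0.75, gt=0, le=1.0)
    kick_fraction: float = Field(default=0.825, gt=0, le=1.0)
    amplitude_sequence: Optional[list[float]] = None


class MotionSpec(BaseModel):
    """Full specification of a synthetic exercise execution."""

    exercise_id: int = Field(ge=1, le=5)
    reps_per_side: int = Field(default=10, ge=1)
    fps: float = Field(default=30.0, gt=0)
    duration_per_rep: float = Field(default=3.2, gt=0)
    rest: float = Field(default=0.5, ge=0)
    calibration: float = Field(default=1.0, gt=0)
    squat_depth: float = Field(default=0.18, gt=0)
    depth_sequence: Optional[list[float]] = None
    phase_lag: float = Field(default=0.0, ge=0)
    leg_order: Optional[list[str]] = None
    left: SideMotion = Field(default_factory=SideMotion)
    right: SideMotion = Field(default_factory=SideMotion)
    template: BodyTemplate = Field(default_factory=BodyTemplate)

    def side(self, s: str) -> SideMotion:
        return self.left if s == "L" else self.right


class NoiseSpec(BaseModel):
    """Sensor imperfection model: Gaussian jitter, resting tremor, inferred joints."""

    jitter_sigma: float = Field(default=0.0, ge=0)
    tremor_amplitude: float = Field(default=0.0, ge=0)
    tremor_freq: float = Field(default=5.0, gt=0)    # 4-6 Hz typical resting tremor
    inferred_prob: float = Field(default=0.0, ge=0, le=1.0)
    seed: int = 0


@dataclass
class RepTruth:
    """Analytic ground truth of one generated repetition."""

    side: str
    index: int
    t_start: float
    t_end: float
    kind: str                       # "circular" | "vertical"
    complete: bool = True           # circular: full circle traced
    extent_si: Optional[float] = None
    extent_ap: Optional[float] = None
    crossings: Optional[int] = None  # quadrant boundaries crossed per partial leg
    opening_angle: Optional[float] = None
    travel: Optional[float] = None
    tilt: Optional[float] = None


@dataclass
class GroundTruth:
    """Ground truth for a generated stream: per-rep records + expected results."""

    exercise_id: int
    records: list[RepTruth]
    spec: MotionSpec

    def expected(self, config: Optional[ExerciseConfig] = None) -> dict:
        """Expected counters/metrics under ``config`` (default config if None).

        Derived analytically from the construction parameters: thresholds are
        resolved against the template body and each repetition's outcome
        follows from its analytic amplitudes -- never from the detectors.
        """
        if config is None:
            config = ExerciseConfig(exercise_id=self.exercise_id)
        body = self.spec.template.body_metrics(config.arm_segment)
        cfg = resolve_defaults(config, body)
        if self.exercise_id in (1, 4):
            return self._expected_circular(cfg, body)
        if self.exercise_id == 2:
            return self._expected_vertical(cfg, body, sides=("mid",))
        return self._expected_vertical(cfg, body, sides=("L", "R"))

    def _outcome_circular(self, rec: RepTruth, cfg: ExerciseConfig) -> list[str]:
        """Outcomes contributed by one circular repetition, in order."""
        if rec.complete:
            ok = True
            if self.exercise_id == 1 and rec.opening_angle is not None:
                ok = rec.opening_angle >= cfg.arm_extension_min_angle
            if self.exercise_id == 4 and self.spec.phase_lag > cfg.unison_lag_tol:
                ok = False
            return [SUCCESS if ok else FAIL]
        # a partial trace: each abandoned half-circle leg fails at the next
        # direction reversal; both legs fail when they cross >= 2 quadrant
        # boundaries, and the final retrace leg is dropped at stream end.
        return [FAIL, FAIL] if (rec.crossings or 0) >= 2 else []

    def _expected_circular(self, cfg: ExerciseConfig, body: BodyMetrics) -> dict:
        counters = Counters()
        metrics: dict = {}
        for side in ("L", "R"):
            recs = [r for r in self.records if r.side == side]
            outcomes: list[str] = []
            ext: list[tuple[float, float]] = []
            for r in recs:
                out = self._outcome_circular(r, cfg)
                outcomes.extend(out)
                ext.extend([(r.extent_si, r.extent_ap)] * sum(o == SUCCESS for o in out))
            if outcomes and not any(o == SUCCESS for o in outcomes) \
                    and not recs[0].complete:
                outcomes = outcomes[:-1]  # final retrace leg dropped at stream end
            s = f = 0
            counted: list[tuple[float, float]] = []
            si_iter = iter(ext)
            for o in outcomes:
                if s >= cfg.N:
                    break
                if o == SUCCESS:
                    s += 1
                    counted.append(next(si_iter))
                else:
                    f += 1
            setattr(counters, f"{side}_s", s)
            setattr(counters, f"{side}_f", f)
            metrics[f"{side}_f"] = f
            metrics[f"circularity_{side}"] = (
                float(np.mean([c[0] for c in counted]) / np.mean([c[1] for c in counted]))
                if counted else None)
        complete = counters.L_s == cfg.N and counters.R_s == cfg.N
        return {"counters": counters, "metrics": metrics, "complete": complete}

    def _expected_vertical(self, cfg: ExerciseConfig, body: BodyMetrics,
                           sides: tuple[str, ...]) -> dict:
        counters = Counters()
        metrics: dict = {}
        for side in sides:
            recs = [r for r in self.records if r.side == side]
            if self.exercise_id == 2:
                thr, norm, inclusive = float(cfg.D_min), float(cfg.D_min), False
            elif self.exercise_id == 3:
                arm = body.segment(f"{side}_Arm")
                thr = getattr(cfg, f"height_ratio_{side}") * arm
                norm, inclusive = arm, True
            else:
                thr, inclusive = float(cfg.H_min), False
                norm = body.segment(f"{side}_Shin")
            s = f = 0
            counted: list[float] = []
            for r in recs:
                if s >= cfg.N:
                    break
                ok = (r.travel >= thr) if inclusive else (r.travel > thr)
                if self.exercise_id == 3 and (r.tilt or 0.0) > cfg.forearm_vertical_tol:
                    ok = False
                if ok:
                    s += 1
                    counted.append(r.travel)
                else:
                    f += 1
            mean_travel = float(np.mean(counted)) if counted else None
            if side == "mid":
                counters.M_s, counters.M_f = s, f
                metrics["M_f"] = f
                metrics["mean_depth_pct"] = (
                    None if mean_travel is None else 100.0 * mean_travel / norm)
            else:
                setattr(counters, f"{side}_s", s)
                setattr(counters, f"{side}_f", f)
                metrics[f"{side}_f"] = f
                metrics[f"mean_height_pct_{side}"] = (
                    None if mean_travel is None else 100.0 * mean_travel / norm)
        if sides == ("mid",):
            complete = counters.M_s == cfg.N
        else:
            complete = counters.L_s == cfg.N and counters.R_s == cfg.N
        return {"counters": counters, "metrics": metrics, "complete": complete}


# ---------------------------------------------------------------------------
# pose construction
# ---------------------------------------------------------------------------

_ANKLE_Y = 0.08
_HIP_HALF_WIDTH = 0.12
_SHOULDER_HALF_WIDTH = 0.18
_FOOT_OFFSET = np.array([0.0, -0.04, 0.12])


def _base_pose(tmpl: BodyTemplate, posture: str) -> np.ndarray:
    """Rest pose, shape (20, 3); arms hang relaxed at the sides."""
    p = np.zeros((N_JOINTS, 3))

    def put(name, x, y, z):
        p[JOINT_INDEX[name]] = (x, y, z)

    knee_y = _ANKLE_Y + tmpl.shin
    if posture == "standing":
        hip_y, hip_z = knee_y + tmpl.thigh, 0.0
    else:  # seated: thigh horizontal, pelvis behind the knees
        hip_y, hip_z = knee_y, -tmpl.thigh
    for side, sx in (("L", 1.0), ("R", -1.0)):
        put(f"Ankle{side}", sx * _HIP_HALF_WIDTH, _ANKLE_Y, 0.0)
        put(f"Knee{side}", sx * _HIP_HALF_WIDTH, knee_y, 0.0)
        put(f"Hip{side}", sx * _HIP_HALF_WIDTH, hip_y, hip_z)
        p[JOINT_INDEX[f"Foot{side}"]] = p[JOINT_INDEX[f"Ankle{side}"]] + _FOOT_OFFSET
    put("HipCenter", 0.0, hip_y, hip_z)
    put("Spine", 0.0, hip_y + 0.20, hip_z)
    put("ShoulderCenter", 0.0, hip_y + 0.45, hip_z)
    put("Head", 0.0, hip_y + 0.62, hip_z)
    for side, sx in (("L", 1.0), ("R", -1.0)):
        sh = np.array([sx * _SHOULDER_HALF_WIDTH, hip_y + 0.42, hip_z])
        p[JOINT_INDEX[f"Shoulder{side}"]] = sh
        p[JOINT_INDEX[f"Elbow{side}"]] = sh + [0.0, -tmpl.upper_arm, 0.0]
        p[JOINT_INDEX[f"Wrist{side}"]] = sh + [0.0, -tmpl.upper_arm - tmpl.forearm, 0.0]
        p[JOINT_INDEX[f"Hand{side}"]] = sh + [0.0, -tmpl.upper_arm - tmpl.forearm - 0.08, 0.0]
    return p


def _ik2(p_from: np.ndarray, p_to: np.ndarray, l1: float, l2: float,
         ref: np.ndarray) -> np.ndarray:
    """Middle joint of a two-link chain, displaced toward ``ref``; vectorized.

    ``p_from``/``p_to`` are (n, 3); the joint sits at distance ``l1`` from
    ``p_from`` and ``l2`` from ``p_to``, offset perpendicular to the chain in
    the direction of ``ref`` (projected off the chain axis).
    """
    d = p_to - p_from
    m = np.linalg.norm(d, axis=1)
    if np.any(m > l1 + l2 + 1e-9) or np.any(m < abs(l1 - l2) - 1e-9):
        raise MotionSpecError("two-link chain target out of reach")
    m = np.clip(m, abs(l1 - l2) + 1e-12, l1 + l2)
    axis = d / m[:, None]
    a = (l1 * l1 - l2 * l2 + m * m) / (2.0 * m)
    h = np.sqrt(np.maximum(l1 * l1 - a * a, 0.0))
    perp = ref[None, :] - (axis @ ref)[:, None] * axis
    pn = np.linalg.norm(perp, axis=1)
    fallback = np.array([0.0, 0.0, 1.0])
    perp = np.where(pn[:, None] > 1e-9, perp / np.maximum(pn, 1e-12)[:, None],
                    fallback[None, :])
    return p_from + a[:, None] * axis + h[:, None] * perp


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

@dataclass
class _Timeline:
    fps: float
    n_cal: int
    n_move: int
    n_rest: int
    n_reps: int

    @property
    def n_total(self) -> int:
        return self.n_cal + self.n_reps * (self.n_move + self.n_rest)

    def rep_bounds(self, k: int) -> tuple[int, int]:
        start = self.n_cal + k * (self.n_move + self.n_rest)
        return start, start + self.n_move

    def phase(self) -> np.ndarray:
        """Within-repetition phase u in [0, 1); 0 outside movement blocks."""
        u = np.zeros(self.n_total)
        for k in range(self.n_reps):
            a, b = self.rep_bounds(k)
            u[a:b] = np.arange(self.n_move) / self.n_move
        return u

    def rep_index(self) -> np.ndarray:
        """Repetition index per frame (-1 outside movement blocks)."""
        r = np.full(self.n_total, -1, dtype=int)
        for k in range(self.n_reps):
            a, b = self.rep_bounds(k)
            r[a:b] = k
        return r


def _timeline(spec: MotionSpec, n_reps: int) -> _Timeline:
    return _Timeline(fps=spec.fps,
                     n_cal=int(round(spec.calibration * spec.fps)),
                     n_move=int(round(spec.duration_per_rep * spec.fps)),
                     n_rest=int(round(spec.rest * spec.fps)),
                     n_reps=n_reps)


def _raised_cosine(u: np.ndarray) -> np.ndarray:
    """0 -> 1 -> 0 profile with zero end slopes; peak exactly at u = 0.5."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * u))


def _circle_phase(u: np.ndarray, active: np.ndarray, fraction: float) -> np.ndarray:
    """Circle angle psi (radians from superior, rotating toward anterior)."""
    psi = np.zeros_like(u)
    if fraction >= 1.0:
        psi[active] = 2.0 * np.pi * u[active]
    else:
        tri = np.where(u <= 0.5, 2.0 * u, 2.0 * (1.0 - u))
        psi[active] = 2.0 * np.pi * fraction * tri[active]
    return psi


def _delay(arr: np.ndarray, shift: int) -> np.ndarray:
    if shift <= 0:
        return arr
    out = np.empty_like(arr)
    out[:shift] = arr[0]
    out[shift:] = arr[:-shift]
    return out


def _partial_crossings(fraction: float) -> int:
    """Quadrant boundaries crossed by one leg of a partial circle from the top."""
    sweep = 360.0 * fraction
    return sum(sweep > b for b in (45.0, 135.0, 225.0, 315.0))


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def generate_stream(spec: MotionSpec) -> tuple[SkeletonStream, GroundTruth]:
    """Generate a noiseless exercise execution and its analytic ground truth.

    The construction is deterministic: the same spec always yields the same
    stream.  Segment lengths match the body template at every frame.
    """
    builders = {1: _gen_arm_circles, 2: _gen_squats, 3: _gen_elbow_lifts,
                4: _gen_stick_circles, 5: _gen_leg_kicks}
    pos, tl, records = builders[spec.exercise_id](spec)
    n = pos.shape[0]
    t = np.arange(n) / spec.fps
    stream = SkeletonStream(t=t, pos=pos, tracked=np.ones((n, N_JOINTS), dtype=bool),
                            nominal_fps=spec.fps)
    return stream, GroundTruth(exercise_id=spec.exercise_id, records=records, spec=spec)


def _tile(base: np.ndarray, n: int) -> np.ndarray:
    return np.repeat(base[None, :, :], n, axis=0)


def _circle_wrist(spec: MotionSpec, side: str, shoulder: np.ndarray,
                  psi: np.ndarray, chord: float, sx: float) -> np.ndarray:
    sm = spec.side(side)
    wy = sm.radius_v * np.cos(psi)
    wz = sm.radius_u * np.sin(psi)
    wx2 = chord * chord - wy * wy - wz * wz
    if np.any(wx2 <= 0):
        raise MotionSpecError("circle radius exceeds arm reach")
    return shoulder[None, :] + np.stack([sx * np.sqrt(wx2), wy, wz], axis=1)


def _gen_arm_circles(spec: MotionSpec):
    tmpl = spec.template
    tl = _timeline(spec, spec.reps_per_side)
    n = tl.n_total
    base = _base_pose(tmpl, "standing")
    pos = _tile(base, n)
    u = tl.phase()
    active = tl.rep_index() >= 0
    lag = int(round(spec.phase_lag * spec.fps))
    records: list[RepTruth] = []
    for side, sx in (("L", 1.0), ("R", -1.0)):
        sm = spec.side(side)
        bend = math.radians(sm.arm_bend_deg)
        lu, lf = tmpl.upper_arm, tmpl.forearm
        chord = math.sqrt(lu * lu + lf * lf - 2.0 * lu * lf * math.cos(bend))
        psi = _circle_phase(u, active, sm.partial_fraction)
        if side == "R":
            psi = _delay(psi, lag)
        shoulder = base[JOINT_INDEX[f"Shoulder{side}"]]
        wrist = _circle_wrist(spec, side, shoulder, psi, chord, sx)
        if sm.arm_bend_deg >= 180.0:
            elbow = shoulder[None, :] + (wrist - shoulder[None, :]) * (lu / chord)
        else:
            elbow = _ik2(np.repeat(shoulder[None, :], n, axis=0), wrist, lu, lf,
                         np.array([0.0, -1.0, 0.0]))
        hand_dir = wrist - elbow
        hand = wrist + hand_dir / np.linalg.norm(hand_dir, axis=1)[:, None] * 0.08
        pos[:, JOINT_INDEX[f"Wrist{side}"]] = wrist
        pos[:, JOINT_INDEX[f"Elbow{side}"]] = elbow
        pos[:, JOINT_INDEX[f"Hand{side}"]] = hand
        for k in range(tl.n_reps):
            a, b = tl.rep_bounds(k)
            records.append(RepTruth(
                side=side, index=k + 1, t_start=(a + (lag if side == "R" else 0)) / spec.fps,
                t_end=(b - 1 + (lag if side == "R" else 0)) / spec.fps,
                kind="circular", complete=sm.partial_fraction >= 1.0,
                extent_si=2.0 * sm.radius_v, extent_ap=2.0 * sm.radius_u,
                crossings=_partial_crossings(sm.partial_fraction),
                opening_angle=sm.arm_bend_deg))
    return pos, tl, records


def _gen_squats(spec: MotionSpec):
    tmpl = spec.template
    depths = spec.depth_sequence or [spec.squat_depth] * spec.reps_per_side
    if any(d <= 0 or d > tmpl.thigh + tmpl.shin - 0.05 for d in depths):
        raise MotionSpecError("squat depth must be positive and leave the legs reachable")
    tl = _timeline(spec, len(depths))
    n = tl.n_total
    base = _base_pose(tmpl, "standing")
    pos = _tile(base, n)
    prof = _raised_cosine(tl.phase())
    rep = tl.rep_index()
    depth_per_frame = np.where(rep >= 0, np.take(np.asarray(depths), np.maximum(rep, 0)), 0.0)
    delta = depth_per_frame * prof
    upper = ["HipCenter", "Spine", "ShoulderCenter", "Head",
             "ShoulderL", "ElbowL", "WristL", "HandL",
             "ShoulderR", "ElbowR", "WristR", "HandR", "HipL", "HipR"]
    # arms extended to the front for the duration of the exercise
    for side in ("L", "R"):
        sh = base[JOINT_INDEX[f"Shoulder{side}"]]
        pos[:, JOINT_INDEX[f"Elbow{side}"]] = sh + [0.0, 0.0, tmpl.upper_arm]
        pos[:, JOINT_INDEX[f"Wrist{side}"]] = sh + [0.0, 0.0, tmpl.upper_arm + tmpl.forearm]
        pos[:, JOINT_INDEX[f"Hand{side}"]] = sh + [0.0, 0.0, tmpl.upper_arm + tmpl.forearm + 0.08]
    for name in upper:
        pos[:, JOINT_INDEX[name], 1] -= delta
    for side in ("L", "R"):
        hip = pos[:, JOINT_INDEX[f"Hip{side}"]]
        ankle = pos[:, JOINT_INDEX[f"Ankle{side}"]]
        pos[:, JOINT_INDEX[f"Knee{side}"]] = _ik2(ankle, hip, tmpl.shin, tmpl.thigh,
                                                  np.array([0.0, 0.0, 1.0]))
    records = [RepTruth(side="mid", index=k + 1, t_start=tl.rep_bounds(k)[0] / spec.fps,
                        t_end=(tl.rep_bounds(k)[1] - 1) / spec.fps, kind="vertical",
                        travel=float(d))
               for k, d in enumerate(depths)]
    return pos, tl, records


def _gen_elbow_lifts(spec: MotionSpec):
    tmpl = spec.template
    tl = _timeline(spec, spec.reps_per_side)
    n = tl.n_total
    base = _base_pose(tmpl, "standing")
    pos = _tile(base, n)
    u = tl.phase()
    prof = _raised_cosine(u)
    rep = tl.rep_index()
    records: list[RepTruth] = []
    for side, sx in (("L", 1.0), ("R", -1.0)):
        sm = spec.side(side)
        fractions = sm.amplitude_sequence or [sm.lift_fraction] * tl.n_reps
        if len(fractions) != tl.n_reps or any(not (0 < h <= 1) for h in fractions):
            raise MotionSpecError("lift fractions must be in (0, 1], one per repetition")
        h = np.where(rep >= 0, np.take(np.asarray(fractions), np.maximum(rep, 0)), 0.0)
        alpha = np.arccos(1.0 - h * prof)
        tilt = math.radians(sm.forearm_tilt_deg)
        sh = base[JOINT_INDEX[f"Shoulder{side}"]]
        elbow = sh[None, :] + tmpl.upper_arm * np.stack(
            [sx * np.sin(alpha), -np.cos(alpha), np.zeros(n)], axis=1)
        fore = np.array([sx * math.sin(tilt), -math.cos(tilt), 0.0])
        wrist = elbow + tmpl.forearm * fore[None, :]
        pos[:, JOINT_INDEX[f"Elbow{side}"]] = elbow
        pos[:, JOINT_INDEX[f"Wrist{side}"]] = wrist
        pos[:, JOINT_INDEX[f"Hand{side}"]] = wrist + 0.08 * fore[None, :]
        for k, frac in enumerate(fractions):
            a, b = tl.rep_bounds(k)
            records.append(RepTruth(side=side, index=k + 1, t_start=a / spec.fps,
                                    t_end=(b - 1) / spec.fps, kind="vertical",
                                    travel=tmpl.upper_arm * float(frac),
                                    tilt=sm.forearm_tilt_deg))
    return pos, tl, records


def _gen_stick_circles(spec: MotionSpec):
    tmpl = spec.template
    tl = _timeline(spec, spec.reps_per_side)
    n = tl.n_total
    base = _base_pose(tmpl, "seated")
    pos = _tile(base, n)
    u = tl.phase()
    active = tl.rep_index() >= 0
    lag = int(round(spec.phase_lag * spec.fps))
    records: list[RepTruth] = []
    for side, sx in (("L", 1.0), ("R", -1.0)):
        sm = spec.side(side)
        psi = _circle_phase(u, active, sm.partial_fraction)
        if side == "R":
            psi = _delay(psi, lag)
        sh = base[JOINT_INDEX[f"Shoulder{side}"]]
        center = sh + np.array([0.0, 0.12, 0.30])
        wrist = center[None, :] + np.stack(
            [np.zeros(n), sm.radius_v * np.cos(psi), sm.radius_u * np.sin(psi)], axis=1)
        elbow = _ik2(np.repeat(sh[None, :], n, axis=0), wrist,
                     tmpl.upper_arm, tmpl.forearm, np.array([sx, 0.0, 0.0]))
        pos[:, JOINT_INDEX[f"Wrist{side}"]] = wrist
        pos[:, JOINT_INDEX[f"Elbow{side}"]] = elbow
        pos[:, JOINT_INDEX[f"Hand{side}"]] = wrist + np.array([-sx * 0.06, 0.0, 0.0])
        for k in range(tl.n_reps):
            a, b = tl.rep_bounds(k)
            records.append(RepTruth(
                side=side, index=k + 1, t_start=(a + (lag if side == "R" else 0)) / spec.fps,
                t_end=(b - 1 + (lag if side == "R" else 0)) / spec.fps,
                kind="circular", complete=sm.partial_fraction >= 1.0,
                extent_si=2.0 * sm.radius_v, extent_ap=2.0 * sm.radius_u,
                crossings=_partial_crossings(sm.partial_fraction)))
    return pos, tl, records


def _gen_leg_kicks(spec: MotionSpec):
    tmpl = spec.template
    order = spec.leg_order or [s for _ in range(spec.reps_per_side) for s in ("L", "R")]
    if set(order) - {"L", "R"}:
        raise MotionSpecError("leg_order entries must be 'L' or 'R'")
    tl = _timeline(spec, len(order))
    n = tl.n_total
    base = _base_pose(tmpl, "seated")
    pos = _tile(base, n)
    prof = _raised_cosine(tl.phase())
    rep = tl.rep_index()
    per_side_count = {"L": 0, "R": 0}
    fr_idx = {"L": 0, "R": 0}
    records: list[RepTruth] = []
    beta = {side: np.zeros(n) for side in ("L", "R")}
    for k, side in enumerate(order):
        sm = spec.side(side)
        fractions = sm.amplitude_sequence
        h = (fractions[fr_idx[side]] if fractions else sm.kick_fraction)
        fr_idx[side] += 1
        if not (0 < h <= 1):
            raise MotionSpecError("kick fraction must be in (0, 1]")
        mask = rep == k
        beta[side][mask] = np.arccos(1.0 - h * prof[mask])
        a, b = tl.rep_bounds(k)
        per_side_count[side] += 1
        records.append(RepTruth(side=side, index=per_side_count[side],
                                t_start=a / spec.fps, t_end=(b - 1) / spec.fps,
                                kind="vertical", travel=tmpl.shin * float(h)))
    for side in ("L", "R"):
        bb = beta[side]
        knee = base[JOINT_INDEX[f"Knee{side}"]]
        ankle = knee[None, :] + tmpl.shin * np.stack(
            [np.zeros(n), -np.cos(bb), np.sin(bb)], axis=1)
        # foot offset rotates rigidly with the shin
        oy, oz = _FOOT_OFFSET[1], _FOOT_OFFSET[2]
        foot = ankle + np.stack(
            [np.zeros(n), oy * np.cos(bb) + oz * np.sin(bb),
             -oy * np.sin(bb) + oz * np.cos(bb)], axis=1)
        pos[:, JOINT_INDEX[f"Ankle{side}"]] = ankle
        pos[:, JOINT_INDEX[f"Foot{side}"]] = foot
    return pos, tl, records


# ---------------------------------------------------------------------------
# sensor noise
# ---------------------------------------------------------------------------

_TREMOR_JOINTS = ("WristL", "HandL", "WristR", "HandR")


def corrupt_stream(stream: SkeletonStream, noise: NoiseSpec) -> SkeletonStream:
    """Overlay sensor imperfections on a stream; reproducible given the seed.

    Adds isotropic Gaussian jitter to every joint, a sinusoidal resting-tremor
    displacement to hands and wrists (random fixed direction and phase per
    joint), and flips joint states to inferred with ``inferred_prob``.
    Frame count and timestamps are unchanged.
    """
    rng = np.random.default_rng(noise.seed)
    out = stream.copy()
    n = len(out)
    if noise.jitter_sigma > 0:
        out.pos = out.pos + rng.normal(0.0, noise.jitter_sigma, size=out.pos.shape)
    if noise.tremor_amplitude > 0:
        for name in _TREMOR_JOINTS:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            wave = noise.tremor_amplitude * np.sin(
                2.0 * np.pi * noise.tremor_freq * out.t + phase)
            out.pos[:, JOINT_INDEX[name]] += wave[:, None] * direction[None, :]
    if noise.inferred_prob > 0:
        flips = rng.random(size=(n, N_JOINTS)) < noise.inferred_prob
        out.tracked = out.tracked & ~flips
    return out
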