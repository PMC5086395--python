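"""Signal-level primitives for repetition detection.

This module holds the pieces the exercise engines are assembled from:

* jitter suppression (centered moving average over joint trajectories),
* joint angles (opening angle at a vertex, segment-vs-vertical angle),
* quadrant encoding of planar trajectories with a hysteresis deadband,
* a circular-repetition state machine (superior-anterior-inferior-posterior
  sequencing, either rotational direction), and
* a vertical-displacement repetition detector with baseline hysteresis.

Quadrants use anatomical labels.  In a body-plane projection ``(u, v)``, u is
the anterior axis and v the superior axis; a displacement from the motion
center is classified by its dominant component:

================  =======================
label             dominant displacement
================  =======================
``superior``      +v
``anterior``      +u
``inferior``      -v
``posterior``     -u
================  =======================

Points whose displacement magnitude is below the deadband radius carry no
label; exact diagonal ties keep the previously emitted label (hysteresis in
label space).  Both conventions suppress the centimeter-scale positional
jitter of consumer depth sensors without masking macroscopic movement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGeometryError,
    InputError,
    ParameterError,
    UndefinedMetricError,
)
from .skeleton import SkeletonStream

SUPERIOR = "superior"
ANTERIOR = "anterior"
INFERIOR = "inferior"
POSTERIOR = "posterior"

#: quadrants in the order traversed by a superior->anterior->inferior->posterior
#: rotation (the "clockwise" direction when u points right and v up).
QUADRANT_ORDER: tuple[str, ...] = (SUPERIOR, ANTERIOR, INFERIOR, POSTERIOR)
_QIDX = {q: i for i, q in enumerate(QUADRANT_ORDER)}

SUCCESS = "success"
FAIL = "fail"


@dataclass
class RepEvent:
    """One detected repetition (successful or failed).

    Circular repetitions carry the superior-inferior and anterior-posterior
    extents of the wrist path; vertical repetitions carry the maximal travel
    away from baseline.  Only the fields relevant to the repetition kind are
    populated.
    """

    outcome: str
    t_start: float
    t_end: float
    side: Optional[str] = None
    index: Optional[int] = None
    extent_superior_inferior: Optional[float] = None
    extent_anterior_posterior: Optional[float] = None
    vertical_travel: Optional[float] = None

    def __post_init__(self) -> None:
        if self.outcome not in (SUCCESS, FAIL):
            raise ParameterError(f"bad outcome {self.outcome!r}")
        if not self.t_start < self.t_end:
            raise ParameterError(f"t_start {self.t_start} must precede t_end {self.t_end}")

    def to_dict(self) -> dict:
        d = {"outcome": self.outcome, "t_start": self.t_start, "t_end": self.t_end}
        for k in ("side", "index", "extent_superior_inferior",
                  "extent_anterior_posterior", "vertical_travel"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d


@dataclass
class Transition:
    """A quadrant-boundary crossing: the wrist entered ``to`` coming from ``from_``."""

    t: float
    from_: str
    to: str
    direction: int  # +1 = S->A->I->P order, -1 = reverse


# ---------------------------------------------------------------------------
# smoothing and angles
# ---------------------------------------------------------------------------

def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 0 with symmetrically shrinking edges.

    At index ``i`` the half-width is ``min(window // 2, i, n - 1 - i)`` so the
    filter stays centered (and unbiased for linear trends) near the ends.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be an odd integer >= 1, got {window}")
    x = np.asarray(values, dtype=float)
    n = x.shape[0]
    if window == 1 or n == 1:
        return x.copy()
    half = window // 2
    cs = np.concatenate([np.zeros((1,) + x.shape[1:]), np.cumsum(x, axis=0)], axis=0)
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo, hi = idx - h, idx + h + 1
    counts = (hi - lo).reshape((n,) + (1,) * (x.ndim - 1))
    return (cs[hi] - cs[lo]) / counts


def smooth_stream(stream: SkeletonStream, window_frames: int = 5) -> SkeletonStream:
    """Suppress random joint positional jitter with a centered moving average.

    Timestamps and tracking states are unchanged; ``window_frames`` must be odd.
    """
    out = stream.copy()
    out.pos = moving_average(stream.pos, window_frames)
    return out


def opening_angle(a, b, c) -> float:
    """Angle (degrees, in [0, 180]) at vertex ``b`` between rays b->a and b->c.

    180 degrees means the three joints are collinear, i.e. a fully extended
    limb when applied to shoulder-elbow-wrist.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    u, v = a - b, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DegenerateGeometryError("zero-length ray in opening angle")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def opening_angles(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorized :func:`opening_angle` over ``(n, 3)`` joint trajectories."""
    u, v = a - b, c - b
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    if np.any(nu == 0) or np.any(nv == 0):
        raise DegenerateGeometryError("zero-length ray in opening angle")
    cosang = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


_DOWN = np.array([0.0, -1.0, 0.0])


def segment_vertical_angle(upper, lower) -> float:
    """Angle (degrees) between the segment upper->lower and the downward vertical.

    0 = a perfectly vertical hanging segment (e.g. a forearm with the wrist
    directly below the elbow); 90 = horizontal.
    """
    u = np.asarray(lower, dtype=float) - np.asarray(upper, dtype=float)
    n = np.linalg.norm(u)
    if n == 0:
        raise DegenerateGeometryError("coincident points in segment_vertical_angle")
    cosang = np.clip(np.dot(u, _DOWN) / n, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def segment_vertical_angles(upper: np.ndarray, lower: np.ndarray) -> np.ndarray:
    """Vectorized :func:`segment_vertical_angle` over ``(n, 3)`` trajectories."""
    u = np.asarray(lower, dtype=float) - np.asarray(upper, dtype=float)
    n = np.linalg.norm(u, axis=1)
    if np.any(n == 0):
        raise DegenerateGeometryError("coincident points in segment_vertical_angle")
    cosang = np.clip(-u[:, 1] / n, -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


# ---------------------------------------------------------------------------
# quadrant encoding
# ---------------------------------------------------------------------------

def classify_quadrant(du: float, dv: float, deadband: float,
                      previous: Optional[str]) -> Optional[str]:
    """Quadrant of a displacement, or None inside the deadband / on a dead tie."""
    if du * du + dv * dv <= deadband * deadband:
        return None
    au, av = abs(du), abs(dv)
    if av > au:
        return SUPERIOR if dv > 0 else INFERIOR
    if au > av:
        return ANTERIOR if du > 0 else POSTERIOR
    return previous  # exact diagonal: keep the previous label


def quadrant_sequence(traj: Sequence, center, deadband_radius: float) -> list[str]:
    """Collapsed quadrant labels of a planar trajectory about a fixed center.

    Points inside the deadband emit no label; consecutive duplicates are
    collapsed; exact diagonal ties keep the previously emitted label.
    """
    if deadband_radius < 0:
        raise ParameterError("deadband_radius must be >= 0")
    cu, cv = float(center[0]), float(center[1])
    labels: list[str] = []
    prev: Optional[str] = None
    for p in traj:
        lab = classify_quadrant(float(p[0]) - cu, float(p[1]) - cv, deadband_radius, prev)
        if lab is None:
            continue
        if lab != prev:
            labels.append(lab)
            prev = lab
    return labels


# ---------------------------------------------------------------------------
# circular repetition detection
# ---------------------------------------------------------------------------

@dataclass
class CircularParams:
    """Tunables of the circular-repetition detector.

    deadband: radius (m) around the motion center inside which no quadrant is
        assigned; suppresses sensor jitter.
    max_rep_duration: an attempt open longer than this (s) is closed as a fail
        when it already covered at least half a circle, else discarded.
    center_window: total width (s) of the centered window whose axis-aligned
        bounding-box midpoint serves as the running motion-center estimate.
    """

    deadband: float = 0.03
    max_rep_duration: float = 10.0
    center_window: float = 2.0
    stationary_window: float = 0.5

    def __post_init__(self) -> None:
        if self.deadband < 0:
            raise ParameterError("deadband must be >= 0")
        if self.max_rep_duration <= 0 or self.center_window <= 0 \
                or self.stationary_window <= 0:
            raise ParameterError("durations must be positive")


def _running_centers(traj: np.ndarray, t: np.ndarray, window_s: float) -> np.ndarray:
    """Per-frame motion center: midpoint of the bounding box over a centered window."""
    n = traj.shape[0]
    if n == 1:
        return traj.copy()
    dt = float(np.median(np.diff(t)))
    w = max(1, int(round(window_s / dt)))
    if w % 2 == 0:
        w += 1
    centers = np.empty_like(traj)
    for k in range(2):
        s = pd.Series(traj[:, k])
        lo = s.rolling(w, center=True, min_periods=1).min().to_numpy()
        hi = s.rolling(w, center=True, min_periods=1).max().to_numpy()
        centers[:, k] = 0.5 * (lo + hi)
    return centers


def _moving_mask(traj: np.ndarray, t: np.ndarray, window_s: float,
                 deadband: float) -> np.ndarray:
    """True where the trailing short-window bounding box exceeds the deadband.

    While the subject is (near-)stationary the wrist emits no quadrant
    labels; this suppresses jitter-driven label flips at rest and spurious
    transitions before a movement has actually begun.
    """
    n = traj.shape[0]
    if n == 1:
        return np.zeros(1, dtype=bool)
    dt = float(np.median(np.diff(t)))
    w = max(2, int(round(window_s / dt)))
    moving = np.zeros(n, dtype=bool)
    for k in range(2):
        s = pd.Series(traj[:, k])
        ext = (s.rolling(w, min_periods=1).max()
               - s.rolling(w, min_periods=1).min()).to_numpy()
        moving |= ext > deadband
    return moving


@dataclass
class _Attempt:
    direction: int
    count: int
    t_open: float
    ctx: int           # frame index where the start quadrant was entered
    center: np.ndarray  # center frozen while the attempt is open


def circular_rep_analysis(
    traj: np.ndarray,
    t: np.ndarray,
    params: CircularParams = CircularParams(),
) -> tuple[list[RepEvent], list[Transition]]:
    """Run the circular-repetition state machine on a planar trajectory.

    A *success* is a run of four consecutive quadrant transitions in one
    rotational direction, returning to the starting quadrant (one full
    circle, either direction).  A *fail* is an attempt that covered at least
    half a circle (two same-direction transitions) but was abandoned by a
    direction reversal or by exceeding ``max_rep_duration``.  Opposite-quadrant
    jumps (linear oscillation through the center) carry no rotational
    information and silently reset the attempt.  An attempt still open when
    the trajectory ends is dropped.

    Returns the events plus the full transition log (used by the unison check
    of the broomstick exercise).
    """
    traj = np.asarray(traj, dtype=float)
    t = np.asarray(t, dtype=float)
    events: list[RepEvent] = []
    transitions: list[Transition] = []
    n = traj.shape[0]
    if n == 0:
        return events, transitions
    if traj.shape != (n, 2) or t.shape != (n,):
        raise InputError("traj must be (n, 2) and t (n,)")
    if n > 1 and np.any(np.diff(t) <= 0):
        raise InputError("timestamps must be strictly increasing")

    centers = _running_centers(traj, t, params.center_window)
    moving = _moving_mask(traj, t, params.stationary_window, params.deadband)

    prev: Optional[str] = None
    entered = 0          # frame index where the current quadrant was entered
    attempt: Optional[_Attempt] = None

    def extents(i0: int, i1: int) -> tuple[float, float]:
        seg = traj[i0:i1 + 1]
        return float(np.ptp(seg[:, 1])), float(np.ptp(seg[:, 0]))

    def close_fail(att: _Attempt, i: int) -> None:
        si, ap = extents(att.ctx, i)
        events.append(RepEvent(outcome=FAIL, t_start=float(t[att.ctx]), t_end=float(t[i]),
                               extent_superior_inferior=si, extent_anterior_posterior=ap))

    for i in range(n):
        if attempt is not None and float(t[i]) - attempt.t_open > params.max_rep_duration:
            if attempt.count >= 2:
                close_fail(attempt, i)
            attempt = None
        if not moving[i]:
            continue
        center = attempt.center if attempt is not None else centers[i]
        lab = classify_quadrant(traj[i, 0] - center[0], traj[i, 1] - center[1],
                                params.deadband, prev)
        if lab is None or lab == prev:
            continue
        if prev is None:
            prev, entered = lab, i
            continue
        delta = (_QIDX[lab] - _QIDX[prev]) % 4
        if delta == 2:
            # opposite-quadrant jump: linear motion through the center
            attempt = None
            prev, entered = lab, i
            continue
        direction = 1 if delta == 1 else -1
        transitions.append(Transition(t=float(t[i]), from_=prev, to=lab, direction=direction))
        if attempt is None:
            attempt = _Attempt(direction=direction, count=1, t_open=float(t[i]),
                               ctx=entered, center=centers[i].copy())
        elif attempt.direction != direction:
            if attempt.count >= 2:
                close_fail(attempt, i)
            # the reversal transition itself opens the counter-rotating attempt
            attempt = _Attempt(direction=direction, count=1, t_open=float(t[i]),
                               ctx=entered, center=centers[i].copy())
        else:
            attempt.count += 1
            if attempt.count == 4:
                si, ap = extents(attempt.ctx, i)
                events.append(RepEvent(outcome=SUCCESS, t_start=float(t[attempt.ctx]),
                                       t_end=float(t[i]),
                                       extent_superior_inferior=si,
                                       extent_anterior_posterior=ap))
                attempt = None
        prev, entered = lab, i
    return events, transitions


def detect_circular_reps(
    traj: np.ndarray,
    t: np.ndarray,
    params: CircularParams = CircularParams(),
) -> list[RepEvent]:
    """Detect circular repetitions; see :func:`circular_rep_analysis`."""
    events, _ = circular_rep_analysis(traj, t, params)
    return events


def circularity_metric(events: Sequence[RepEvent]) -> float:
    """Mean superior-inferior extent over mean anterior-posterior extent.

    Computed over successful repetitions; equals 1 for perfect circles and
    (vertical diameter)/(horizontal diameter) for axis-aligned ellipses.
    """
    succ = [e for e in events if e.outcome == SUCCESS]
    if not succ:
        raise UndefinedMetricError("circularity requires at least one successful repetition")
    si = float(np.mean([e.extent_superior_inferior for e in succ]))
    ap = float(np.mean([e.extent_anterior_posterior for e in succ]))
    if ap == 0:
        raise UndefinedMetricError("zero mean anterior-posterior extent")
    return si / ap


# ---------------------------------------------------------------------------
# vertical repetition detection
# ---------------------------------------------------------------------------

def detect_vertical_reps(
    t: np.ndarray,
    values: np.ndarray,
    baseline: float,
    threshold: float,
    direction: str = "down",
    hysteresis: float = 0.02,
    max_rep_duration: float = 10.0,
    attempt_floor: float = 2.0,
    inclusive: bool = False,
) -> list[RepEvent]:
    """Detect vertical-displacement repetitions in a height signal.

    A repetition opens when the signal departs from ``baseline`` beyond
    ``hysteresis`` in ``direction`` ('down' for squats, 'up' for lifts/kicks)
    and closes when it returns within ``hysteresis`` of baseline (or at
    stream end, or after ``max_rep_duration``).  Its ``vertical_travel`` is
    the maximal excursion from baseline.  Outcome: success when travel
    exceeds ``threshold`` (``>=`` with ``inclusive=True``); otherwise a fail
    when travel exceeds the attempt floor ``attempt_floor * hysteresis``
    (a genuine attempt, too shallow); smaller excursions emit no event.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    if hysteresis < 0:
        raise ParameterError("hysteresis must be >= 0")
    if direction not in ("up", "down"):
        raise ParameterError(f"direction must be 'up' or 'down', got {direction!r}")
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    if t.shape != values.shape:
        raise InputError("t and values must have equal shapes")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise InputError("timestamps must be strictly increasing")

    exc = (baseline - values) if direction == "down" else (values - baseline)
    floor = attempt_floor * hysteresis
    events: list[RepEvent] = []
    open_i: Optional[int] = None
    peak = 0.0

    def close(i_end: int) -> None:
        nonlocal open_i, peak
        if peak > threshold or (inclusive and peak >= threshold):
            outcome = SUCCESS
        elif peak > floor:
            outcome = FAIL
        else:
            open_i, peak = None, 0.0
            return
        events.append(RepEvent(outcome=outcome, t_start=float(t[open_i]),
                               t_end=float(t[i_end]), vertical_travel=float(peak)))
        open_i, peak = None, 0.0

    for i in range(t.size):
        if open_i is None:
            if exc[i] > hysteresis:
                open_i = i
                peak = float(exc[i])
        else:
            peak = max(peak, float(exc[i]))
            if exc[i] < hysteresis:
                close(i)
            elif float(t[i]) - float(t[open_i]) > max_rep_duration:
                close(i)
    if open_i is not None and t.size - 1 > open_i:
        close(t.size - 1)
    return events
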