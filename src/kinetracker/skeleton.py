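"""Skeleton stream data model, coordinate conventions and body-segment estimation.

The skeleton follows the 20-joint layout produced by first-generation consumer
depth sensors: a torso chain (HipCenter, Spine, ShoulderCenter, Head) plus
Shoulder/Elbow/Wrist/Hand and Hip/Knee/Ankle/Foot chains for each side.

Coordinate frame (right-handed, meters):

* ``+x`` -- the subject's left (transverse axis),
* ``+y`` -- up (superior),
* ``+z`` -- anterior, toward the sensor.

Every joint in every frame carries a tracking state: ``tracked`` for clearly
visible joints, ``inferred`` for joints whose position the sensor SDK
estimated from the rest of the skeleton (e.g. occluded by another body part).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, NamedTuple

import numpy as np

from .errors import (
    CalibrationError,
    DegenerateSkeletonError,
    ParameterError,
    StreamValidationError,
)

JOINT_NAMES: tuple[str, ...] = (
    "HipCenter", "Spine", "ShoulderCenter", "Head",
    "ShoulderL", "ElbowL", "WristL", "HandL",
    "ShoulderR", "ElbowR", "WristR", "HandR",
    "HipL", "KneeL", "AnkleL", "FootL",
    "HipR", "KneeR", "AnkleR", "FootR",
)
JOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(JOINT_NAMES)}
N_JOINTS = len(JOINT_NAMES)

TRACKED = "tracked"
INFERRED = "inferred"
STATES = (TRACKED, INFERRED)

#: body segments estimated during calibration: name -> (proximal, distal) joints
SEGMENT_JOINTS: dict[str, tuple[str, str]] = {
    "L_Thigh": ("HipL", "KneeL"),
    "R_Thigh": ("HipR", "KneeR"),
    "L_Shin": ("KneeL", "AnkleL"),
    "R_Shin": ("KneeR", "AnkleR"),
}
_ARM_JOINTS = {
    "upper": {"L_Arm": ("ShoulderL", "ElbowL"), "R_Arm": ("ShoulderR", "ElbowR")},
    "fore": {"L_Arm": ("ElbowL", "WristL"), "R_Arm": ("ElbowR", "WristR")},
}


class Point2D(NamedTuple):
    """A point in a 2D body-plane projection (meters)."""

    u: float
    v: float


@dataclass
class JointFrame:
    """One timestamped 20-joint snapshot.

    ``joints`` maps each joint name to ``(position, state)`` where position is
    a length-3 array in meters and state is ``tracked`` or ``inferred``.
    """

    t: float
    joints: dict[str, tuple[np.ndarray, str]]

    def __post_init__(self) -> None:
        if self.t < 0:
            raise StreamValidationError(f"negative timestamp {self.t}")
        missing = set(JOINT_NAMES) - set(self.joints)
        if missing:
            raise StreamValidationError(f"frame missing joints: {sorted(missing)}")
        unknown = set(self.joints) - set(JOINT_NAMES)
        if unknown:
            raise StreamValidationError(f"unknown joints: {sorted(unknown)}")
        for name, (pos, state) in self.joints.items():
            if state not in STATES:
                raise StreamValidationError(f"{name}: bad state {state!r}")
            if not np.all(np.isfinite(pos)):
                raise StreamValidationError(f"{name}: non-finite position")


@dataclass
class SkeletonStream:
    """An ordered sequence of skeleton frames; the unit of analysis.

    Stored column-wise for vectorized processing: ``t`` has shape ``(n,)``,
    ``pos`` has shape ``(n, 20, 3)`` (joint order = :data:`JOINT_NAMES`) and
    ``tracked`` is a boolean ``(n, 20)`` mask (False = inferred).
    """

    t: np.ndarray
    pos: np.ndarray
    tracked: np.ndarray
    nominal_fps: float = 30.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        self.tracked = np.asarray(self.tracked, dtype=bool)
        n = self.t.shape[0]
        if n < 1:
            raise StreamValidationError("stream must contain at least one frame")
        if self.pos.shape != (n, N_JOINTS, 3):
            raise StreamValidationError(f"pos shape {self.pos.shape} != {(n, N_JOINTS, 3)}")
        if self.tracked.shape != (n, N_JOINTS):
            raise StreamValidationError(f"tracked shape {self.tracked.shape} != {(n, N_JOINTS)}")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.pos)):
            raise StreamValidationError("non-finite timestamps or positions")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise StreamValidationError("timestamps must be strictly increasing")
            med = float(np.median(dt))
            nominal = 1.0 / self.nominal_fps
            if not (0.5 * nominal <= med <= 1.5 * nominal):
                raise StreamValidationError(
                    f"median frame interval {med:.4f}s is outside +/-50% of "
                    f"nominal {nominal:.4f}s"
                )

    def __len__(self) -> int:
        return int(self.t.shape[0])

    def joint(self, name: str) -> np.ndarray:
        """Positions of one joint over time, shape ``(n, 3)``."""
        return self.pos[:, JOINT_INDEX[name], :]

    def joint_tracked(self, name: str) -> np.ndarray:
        """Boolean tracked mask for one joint, shape ``(n,)``."""
        return self.tracked[:, JOINT_INDEX[name]]

    def frames(self) -> Iterator[JointFrame]:
        for i in range(len(self)):
            joints = {
                name: (self.pos[i, j].copy(), TRACKED if self.tracked[i, j] else INFERRED)
                for j, name in enumerate(JOINT_NAMES)
            }
            yield JointFrame(t=float(self.t[i]), joints=joints)

    @classmethod
    def from_frames(cls, frames: list[JointFrame], nominal_fps: float = 30.0) -> "SkeletonStream":
        n = len(frames)
        t = np.array([f.t for f in frames], dtype=float)
        pos = np.empty((n, N_JOINTS, 3), dtype=float)
        tracked = np.empty((n, N_JOINTS), dtype=bool)
        for i, f in enumerate(frames):
            for j, name in enumerate(JOINT_NAMES):
                p, s = f.joints[name]
                pos[i, j] = np.asarray(p, dtype=float)
                tracked[i, j] = s == TRACKED
        return cls(t=t, pos=pos, tracked=tracked, nominal_fps=nominal_fps)

    def copy(self) -> "SkeletonStream":
        return replace(self, t=self.t.copy(), pos=self.pos.copy(), tracked=self.tracked.copy())

    def translated(self, offset) -> "SkeletonStream":
        """Rigidly translate every frame by ``offset`` (3-vector)."""
        out = self.copy()
        out.pos = out.pos + np.asarray(offset, dtype=float)[None, None, :]
        return out


def mirror_lr(stream: SkeletonStream) -> SkeletonStream:
    """Reflect the subject about the sagittal plane: negate x and swap L/R joints."""
    out = stream.copy()
    perm = np.arange(N_JOINTS)
    for name in JOINT_NAMES:
        if name.endswith("L"):
            perm[JOINT_INDEX[name]] = JOINT_INDEX[name[:-1] + "R"]
        elif name.endswith("R"):
            perm[JOINT_INDEX[name]] = JOINT_INDEX[name[:-1] + "L"]
    out.pos = out.pos[:, perm, :]
    out.tracked = out.tracked[:, perm]
    out.pos[:, :, 0] = -out.pos[:, :, 0]
    return out


@dataclass(frozen=True)
class BodyMetrics:
    """Per-patient body segment lengths (meters), estimated from calibration frames."""

    L_Thigh: float
    R_Thigh: float
    L_Shin: float
    R_Shin: float
    L_Arm: float
    R_Arm: float

    def __post_init__(self) -> None:
        for pair in (("L_Thigh", "R_Thigh"), ("L_Shin", "R_Shin"), ("L_Arm", "R_Arm")):
            a, b = (getattr(self, k) for k in pair)
            if a <= 0 or b <= 0:
                raise DegenerateSkeletonError(f"non-positive segment length in {pair}")
            if max(a, b) > 2.0 * min(a, b):
                raise DegenerateSkeletonError(
                    f"left/right asymmetry beyond factor 2 for {pair}: {a:.3f} vs {b:.3f}"
                )

    def segment(self, name: str) -> float:
        return float(getattr(self, name))


_PLANES = ("sagittal", "frontal")


def project(point, plane: str) -> Point2D:
    """Project a 3D point onto a body plane.

    sagittal -> ``(u, v) = (z, y)``: u is anterior, v is superior.
    frontal  -> ``(u, v) = (x, y)``.
    """
    u, v = _plane_cols(plane)
    p = np.asarray(point, dtype=float)
    return Point2D(float(p[u]), float(p[v]))


def project_points(points: np.ndarray, plane: str) -> np.ndarray:
    """Vectorized :func:`project`: ``(n, 3) -> (n, 2)``."""
    u, v = _plane_cols(plane)
    pts = np.asarray(points, dtype=float)
    return pts[:, (u, v)]


def _plane_cols(plane: str) -> tuple[int, int]:
    if plane == "sagittal":
        return 2, 1
    if plane == "frontal":
        return 0, 1
    raise ParameterError(f"unknown plane {plane!r}; expected one of {_PLANES}")


def calibration_slice(stream: SkeletonStream, calibration_window: float) -> slice:
    """Frame slice covering the initial stationary calibration window."""
    t0 = float(stream.t[0])
    n = int(np.searchsorted(stream.t, t0 + calibration_window, side="left"))
    return slice(0, max(n, 1))


def estimate_body_metrics(
    stream: SkeletonStream,
    calibration_window: float = 1.0,
    arm_segment: str = "upper",
) -> BodyMetrics:
    """Estimate body segment lengths from an initial stationary window.

    Each segment length is the median, over the calibration frames, of the
    Euclidean distance between its two joints.  The median makes the estimate
    robust to isolated tracking glitches.  ``arm_segment`` selects whether the
    arm length is the upper arm (shoulder-elbow, default) or the forearm
    (elbow-wrist).
    """
    if arm_segment not in _ARM_JOINTS:
        raise ParameterError(f"arm_segment must be 'upper' or 'fore', got {arm_segment!r}")
    sl = calibration_slice(stream, calibration_window)
    n_needed = int(round(calibration_window * stream.nominal_fps))
    n_have = sl.stop - sl.start
    if n_have < n_needed:
        raise CalibrationError(
            f"calibration window needs {n_needed} frames, stream provides {n_have}"
        )
    segments = dict(SEGMENT_JOINTS)
    segments.update(_ARM_JOINTS[arm_segment])
    lengths: dict[str, float] = {}
    for seg, (a, b) in segments.items():
        d = np.linalg.norm(stream.joint(a)[sl] - stream.joint(b)[sl], axis=1)
        med = float(np.median(d))
        if med <= 0.01:
            raise DegenerateSkeletonError(f"segment {seg} median length {med:.4f} m <= 1 cm")
        lengths[seg] = med
    return BodyMetrics(**lengths)
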