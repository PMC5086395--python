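"""Readers/writers for the canonical stream formats, configs and session reports.

Canonical stream formats:

* **CSV (long)** -- header ``frame,t,joint,x,y,z,state``; one row per joint
  per frame; joint names exactly the 20 of the skeletal model; state is
  ``tracked`` or ``inferred``.
* **JSONL** -- one frame per line:
  ``{"t": <s>, "joints": {"<name>": {"p": [x, y, z], "s": "tracked"}}}``.

Both writers emit a canonical form: ``write_stream(read_stream(f))`` is
byte-identical to ``f`` for files this module produced.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .errors import StreamParseError, StreamValidationError
from .exercises import Counters, ExerciseConfig, SessionResult
from .kinematics import RepEvent
from .skeleton import JOINT_NAMES, N_JOINTS, SkeletonStream, STATES, TRACKED

PathLike = Union[str, Path]

_CSV_HEADER = ["frame", "t", "joint", "x", "y", "z", "state"]


def _infer_dialect(path: PathLike, dialect: Optional[str]) -> str:
    if dialect is not None:
        return dialect
    suffix = Path(path).suffix.lower()
    if suffix in (".jsonl", ".ndjson"):
        return "jsonl"
    return "csv"


def read_stream(path: PathLike, dialect: Optional[str] = None,
                nominal_fps: float = 30.0) -> SkeletonStream:
    """Read a skeleton stream; raises with a line number on malformed input."""
    dialect = _infer_dialect(path, dialect)
    if dialect == "csv":
        return _read_csv(path, nominal_fps)
    if dialect == "jsonl":
        return _read_jsonl(path, nominal_fps)
    raise StreamParseError(f"unknown dialect {dialect!r}")


def write_stream(stream: SkeletonStream, path: PathLike,
                 dialect: Optional[str] = None) -> None:
    """Write a skeleton stream in a canonical dialect (inferred from suffix)."""
    dialect = _infer_dialect(path, dialect)
    if dialect == "csv":
        _write_csv(stream, path)
    elif dialect == "jsonl":
        _write_jsonl(stream, path)
    else:
        raise StreamParseError(f"unknown dialect {dialect!r}")


def _read_csv(path: PathLike, nominal_fps: float) -> SkeletonStream:
    frames: dict[int, dict] = {}
    times: dict[int, float] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise StreamParseError("line 1: empty file") from None
        if header != _CSV_HEADER:
            raise StreamParseError(f"line 1: header must be {','.join(_CSV_HEADER)}")
        for ln, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 7:
                raise StreamParseError(f"line {ln}: expected 7 fields, got {len(row)}")
            frame_s, t_s, joint, xs, ys, zs, state = row
            if joint not in JOINT_NAMES:
                raise StreamParseError(f"line {ln}: unknown joint {joint!r}")
            if state not in STATES:
                raise StreamParseError(f"line {ln}: unknown state {state!r}")
            try:
                fi = int(frame_s)
                t = float(t_s)
                p = (float(xs), float(ys), float(zs))
            except ValueError as exc:
                raise StreamParseError(f"line {ln}: {exc}") from None
            fr = frames.setdefault(fi, {})
            if joint in fr:
                raise StreamParseError(f"line {ln}: duplicate joint {joint!r} in frame {fi}")
            fr[joint] = (p, state)
            times.setdefault(fi, t)
            if times[fi] != t:
                raise StreamParseError(f"line {ln}: inconsistent time for frame {fi}")
    return _assemble(frames, times, nominal_fps)


def _read_jsonl(path: PathLike, nominal_fps: float) -> SkeletonStream:
    frames: dict[int, dict] = {}
    times: dict[int, float] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise StreamParseError(f"line {ln}: {exc}") from None
            try:
                t = float(obj["t"])
                joints = obj["joints"]
            except (KeyError, TypeError) as exc:
                raise StreamParseError(f"line {ln}: missing field {exc}") from None
            fr = {}
            for name, rec in joints.items():
                if name not in JOINT_NAMES:
                    raise StreamParseError(f"line {ln}: unknown joint {name!r}")
                state = rec.get("s", TRACKED)
                if state not in STATES:
                    raise StreamParseError(f"line {ln}: unknown state {state!r}")
                p = rec.get("p")
                if not (isinstance(p, list) and len(p) == 3):
                    raise StreamParseError(f"line {ln}: joint {name!r} position must be [x,y,z]")
                fr[name] = (tuple(float(v) for v in p), state)
            idx = ln - 1
            frames[idx] = fr
            times[idx] = t
    return _assemble(frames, times, nominal_fps)


def _assemble(frames: dict[int, dict], times: dict[int, float],
              nominal_fps: float) -> SkeletonStream:
    if not frames:
        raise StreamParseError("stream contains no frames")
    order = sorted(frames)
    n = len(order)
    pos = np.empty((n, N_JOINTS, 3))
    tracked = np.empty((n, N_JOINTS), dtype=bool)
    t = np.empty(n)
    for i, fi in enumerate(order):
        fr = frames[fi]
        missing = set(JOINT_NAMES) - set(fr)
        if missing:
            raise StreamValidationError(f"frame {fi} missing joints: {sorted(missing)}")
        t[i] = times[fi]
        for j, name in enumerate(JOINT_NAMES):
            p, state = fr[name]
            pos[i, j] = p
            tracked[i, j] = state == TRACKED
    return SkeletonStream(t=t, pos=pos, tracked=tracked, nominal_fps=nominal_fps)


def _fmt(x: float) -> str:
    return repr(float(x))


def _write_csv(stream: SkeletonStream, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_CSV_HEADER)
        for i in range(len(stream)):
            t = _fmt(stream.t[i])
            for j, name in enumerate(JOINT_NAMES):
                x, y, z = stream.pos[i, j]
                state = TRACKED if stream.tracked[i, j] else "inferred"
                writer.writerow([i, t, name, _fmt(x), _fmt(y), _fmt(z), state])


def _write_jsonl(stream: SkeletonStream, path: PathLike) -> None:
    with open(path, "w") as fh:
        for i in range(len(stream)):
            joints = {
                name: {"p": [float(v) for v in stream.pos[i, j]],
                       "s": TRACKED if stream.tracked[i, j] else "inferred"}
                for j, name in enumerate(JOINT_NAMES)
            }
            fh.write(json.dumps({"t": float(stream.t[i]), "joints": joints},
                                separators=(",", ":")) + "\n")


# ---------------------------------------------------------------------------
# configs and reports
# ---------------------------------------------------------------------------

def load_config(path: PathLike) -> ExerciseConfig:
    """Load and validate an exercise configuration from JSON."""
    with open(path) as fh:
        return ExerciseConfig.model_validate(json.load(fh))


def save_config(config: ExerciseConfig, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(config.model_dump(), fh, indent=2)
        fh.write("\n")


def write_report(result: SessionResult, path: PathLike,
                 summary_path: Optional[PathLike] = None) -> dict:
    """Serialize a session result to a JSON report (plus optional text summary).

    Re-reading the report reproduces counters and metrics exactly.
    """
    document = {"format": "kinetracker-report", "version": 1, **result.to_dict()}
    with open(path, "w") as fh:
        json.dump(document, fh, indent=2)
        fh.write("\n")
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            fh.write(format_summary(result))
    return document


def read_report(path: PathLike) -> SessionResult:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "kinetracker-report":
        raise StreamParseError("not a kinetracker report")
    events = [RepEvent(**{k: v for k, v in e.items()}) for e in doc["events"]]
    return SessionResult(
        exercise_id=doc["exercise_id"],
        config=doc["config"],
        body=doc["body"],
        counters=Counters(**doc["counters"]),
        events=events,
        complete=doc["complete"],
        metrics=doc["metrics"],
        warnings=doc.get("warnings", []),
    )


_EXERCISE_NAMES = {
    1: "arm circles (standing)",
    2: "squats",
    3: "elbow lifts",
    4: "broomstick circles (seated)",
    5: "leg kicks (seated)",
}


def _fmt_metric(v) -> str:
    if v is None:
        return "n/a"
    if isinstance(v, float):
        return f"{v:.2f}"
    return str(v)


def format_summary(result: SessionResult) -> str:
    """Human-readable end-of-exercise summary."""
    c = result.counters
    lines = [
        f"Exercise {result.exercise_id}: {_EXERCISE_NAMES[result.exercise_id]}",
        f"Complete: {'yes' if result.complete else 'no'}",
    ]
    if result.exercise_id == 2:
        lines.append(f"Squats: {c.M_s} successful, {c.M_f} failed")
    else:
        lines.append(f"Left:  {c.L_s} successful, {c.L_f} failed")
        lines.append(f"Right: {c.R_s} successful, {c.R_f} failed")
    lines.append("Metrics:")
    for k, v in result.metrics.items():
        lines.append(f"  {k} = {_fmt_metric(v)}")
    if result.warnings:
        lines.append(f"Warnings: {len(result.warnings)}")
        for w in result.warnings[:10]:
            lines.append(f"  - {w.get('type')}: {w}")
    return "\n".join(lines) + "\n"
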