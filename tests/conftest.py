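"""Shared fixtures: synthetic streams and small trajectory builders."""

import numpy as np
import pytest

from kinetracker import ExerciseConfig, generate_stream, run_exercise
from kinetracker.synthetic import MotionSpec


@pytest.fixture(scope="session")
def perfect_runs():
    """Perfect executions of all five exercises, analysed once per session."""
    out = {}
    for ex in range(1, 6):
        spec = MotionSpec(exercise_id=ex)
        stream, truth = generate_stream(spec)
        result = run_exercise(stream, ExerciseConfig(exercise_id=ex))
        out[ex] = (stream, truth, result)
    return out


def make_circle_traj(cycles: float, points_per_cycle: int, radius_v: float = 0.15,
                     radius_u: float = 0.15, partial: float | None = None,
                     fps: float = 30.0, overshoot: float = 0.3):
    """Planar wrist trajectory: circles (or partial trace-and-retrace) from the top.

    Full-circle trajectories overshoot closure by ``overshoot`` radians so
    that both the detector and a pure winding count see whole circles.
    """
    if partial is None:
        total = 2.0 * np.pi * cycles + overshoot
        step = 2.0 * np.pi / points_per_cycle
        psi = np.arange(0.0, total, step)
    else:
        n = int(round(cycles * points_per_cycle))
        u = np.arange(n) / points_per_cycle
        frac = u - np.floor(u)
        tri = np.where(frac <= 0.5, 2.0 * frac, 2.0 * (1.0 - frac))
        psi = 2.0 * np.pi * partial * tri
    t = np.arange(psi.size) / fps
    traj = np.stack([radius_u * np.sin(psi), radius_v * np.cos(psi)], axis=1)
    return traj, t
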