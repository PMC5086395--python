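# kinetracker

Hardware-free assessment engines for skeletal-tracking physiotherapy
exercises used with Parkinson's disease patients.

Depth-camera exergame platforms guide a patient through simple, repeatable
exercises and score each repetition in real time from the tracked 3D
skeleton. kinetracker reimplements the *assessment* half of such a platform
as a plain Python library + CLI: it consumes recorded 20-joint skeletal
streams (30 Hz, `tracked`/`inferred` state per joint) and emits the per-
exercise counters and performance metrics a physiotherapist would use to
tune exercise difficulty or to quantify left/right mobility differences —
no sensor, game engine, or rendering involved. A synthetic motion simulator
with a tremor/jitter noise model replaces the camera for all testing.

## The five exercises and their metrics

| # | Exercise | Success rule | End-of-exercise metrics |
|---|----------|--------------|--------------------------|
| 1 | Arm circles (standing) | wrist traces a full superior→anterior→inferior→posterior circle (either direction) in the sagittal plane, arm fully extended (opening angle ≥ 160°) | failed reps `L_f`, `R_f`; circularity = ⟨SI extent⟩/⟨AP extent⟩ |
| 2 | Squats | mid-hip vertical travel `D > D_min`, default `D_min = (L_Thigh+R_Thigh)/6` | `M_f`; ⟨D⟩/D_min·100% |
| 3 | Elbow lifts | elbow rise ≥ ratio·arm length (default ratio 0.7, per arm), forearm within 20° of vertical | `L_f`, `R_f`; ⟨H⟩/arm·100% per arm |
| 4 | Broomstick circles (seated) | as (1) without the extension check; both wrists' quadrant transitions in phase within 0.25 s | as exercise 1 |
| 5 | Leg kicks (seated) | ankle rise `H > H_min`, default `H_min = 0.75·(L_Shin+R_Shin)/2`, legs in any order | `L_f`, `R_f`; ⟨H⟩/shin·100% per leg |

Success counters freeze at the target `N` (default 10) per side; the ⟨·⟩
averages run over counted successful repetitions only. Repetition
segmentation uses a quadrant state machine (circles) and baseline
hysteresis (vertical moves) on smoothed trajectories; see
`docs/methods.md` for the full model, thresholds, and limitations.

## Worked example

Generate a perfect execution of exercise 1 (10 circles per arm, radius
0.15 m), analyse it, and print the report:

```sh
$ kinetracker simulate --exercise 1 --reps 10 --out s.csv --truth t.json
$ kinetracker analyze --stream s.csv --exercise 1 --out r.json
$ kinetracker report r.json
Exercise 1: arm circles (standing)
Complete: yes
Left:  10 successful, 0 failed
Right: 10 successful, 0 failed
Metrics:
  L_f = 0
  circularity_L = 1.00
  R_f = 0
  circularity_R = 1.00
```

All 20 repetitions are counted, both failure counters are 0, and the
circularity of each wrist path is 1.00 — the signature of a perfectly
executed set of circles. A patient favouring tall ellipses would push
circularity above 1; abandoning circles halfway would raise `L_f`/`R_f`.
`kinetracker simulate` can inject such imperfect executions (partial
circles, shallow squats, tilted forearms, phase lag, jitter/tremor via
`--noise`/`--seed`); `kinetracker selftest` runs the full
generator→engine recovery loop for all five exercises.

The same pipeline from Python:

```python
from kinetracker import ExerciseConfig, generate_stream, run_exercise
from kinetracker.synthetic import MotionSpec

stream, truth = generate_stream(MotionSpec(exercise_id=2))
result = run_exercise(stream, ExerciseConfig(exercise_id=2))
print(result.counters.M_s, result.metrics["mean_depth_pct"])  # 10 119.74...
```

## Layout

```
src/kinetracker/
  skeleton.py    # stream data model, projections, body-segment estimation
  kinematics.py  # smoothing, angles, quadrant encoding, rep detectors
  exercises.py   # the five engines, counters, metrics
  synthetic.py   # motion generator + ground truth, noise model
  io.py          # CSV/JSONL streams, configs, session reports
  cli.py         # simulate / analyze / report / selftest
```
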