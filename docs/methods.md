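# Methods

## Problem and scope

kinetracker reimplements, without any sensor hardware, the assessment logic
of a depth-camera physiotherapy platform for Parkinson's disease patients
(Hoehn–Yahr stages 1–3): five rule-based exercise engines that segment
repetitions out of a 20-joint skeletal stream (nominally 30 Hz), judge each
repetition against body-proportion-derived thresholds, and report the
end-of-exercise performance metrics a physiotherapist would read off the
screen. Live capture, AR rendering and clinical validation are out of scope;
a synthetic motion simulator stands in for the sensor everywhere.

## Coordinate conventions

Right-handed, meters: +x is the subject's left (transverse axis), +y up
(superior), +z anterior. The sagittal projection drops x (`(u, v) = (z, y)`),
the frontal projection drops z. Readers of the canonical CSV/JSONL stream
formats are expected to normalize into this frame on ingest.

## Body calibration

Every stream is expected to open with ~1 s of stationary posture. Segment
lengths (thigh: hip–knee, shin: knee–ankle, arm: shoulder–elbow) are the
per-segment *median* over the calibration frames of the joint–joint
Euclidean distance; the median makes the estimate robust to isolated
tracking glitches. Vertical baselines (standing mid-hip, relaxed elbow,
seated ankle) are medians over the same window. The source platform
normalizes the elbow-lift metric "as a percentage of the upper arm length"
while calling the same quantity a forearm length elsewhere; we default to
the upper arm — the elbow's vertical travel kinematically equals the
upper-arm length — and expose `arm_segment: upper | fore` to switch
readings.

## Jitter suppression

Three layers suppress the centimeter-scale positional noise of consumer
depth sensors without masking macroscopic movement:

1. a centered 5-frame moving average over every joint coordinate (window
   shrinks symmetrically at stream edges), applied before all detectors;
2. a deadband: no quadrant label is assigned while the wrist's displacement
   from the motion center is below 0.03 m;
3. a stationarity guard: no quadrant labels while the trailing 0.5 s
   bounding box of the trajectory is smaller than the deadband, so a resting
   (or merely trembling) wrist emits no labels at all.

Defaults (deadband 0.03 m, hysteresis 0.02 m, window 5) were chosen against
the ~1 cm jitter scale of the emulated hardware and are all configurable.

## Circular repetition detection (exercises 1 and 4)

The wrist trajectory, projected onto the sagittal plane, is encoded as a
sequence of anatomical quadrants (superior / anterior / inferior /
posterior) of its displacement from a running motion-center estimate.
Exact diagonal ties keep the previous label (hysteresis in label space).

*Motion center.* Midpoint of the axis-aligned bounding box of the
trajectory over a centered ±1 s window, re-estimated each frame and frozen
while a repetition attempt is open. A centered window was chosen over a
trailing one deliberately: analysis here is offline, and a trailing window
lags the wrist at movement onset, which systematically shifts the first
quadrant label one quadrant forward and mis-books the first and last
repetition of a set. With the centered window a 10-circle set is recovered
as exactly 10 successes.

*Counting.* A **success** is four consecutive quadrant transitions in one
rotational direction — back to the starting quadrant, i.e. one full circle,
either direction. A **fail** is an attempt that covered at least half a
circle (two same-direction transitions) but was abandoned by a direction
reversal or by exceeding `max_rep_duration` (10 s). Opposite-quadrant jumps
carry no rotational information and reset the attempt, which is what rejects
vertical, horizontal and diagonal linear oscillations. An attempt still open
at stream end is dropped — hence a single trace-and-retrace half circle is
exactly one fail, and a repeated half-circle pattern over R cycles yields
2R − 1 fails (each abandoned leg fails at the next reversal; the final
retrace leg is dropped).

Each success/fail event records the superior–inferior and
anterior–posterior extents of its points; the **circularity** metric is the
mean SI extent over the mean AP extent of counted successes (1 for circles,
axis ratio for axis-aligned ellipses).

Exercise 1 additionally demotes a detector success to a fail if the
shoulder–elbow–wrist opening angle dropped below 160° (configurable) at any
frame of the repetition — demotion rather than discard, so the effort still
appears in the failure counter. Exercise 4 instead demotes a repetition
whose quadrant transitions have no matching transition on the other wrist
within 0.25 s (the unison tolerance).

## Vertical repetition detection (exercises 2, 3, 5)

A height signal (mid-hip, elbow, or ankle y) is compared against its
calibration baseline with hysteresis: a repetition opens when the excursion
exceeds 0.02 m in the exercise's direction and closes when it returns
within hysteresis of baseline. Its travel is the maximal excursion.
Success: travel > threshold (squat depth `D_min`, kick height `H_min`;
strict inequality per the "deeper than / above" phrasing) or travel ≥
target (elbow lifts, whose targets use "close to" language). A too-shallow
excursion still counts as a failed attempt if it exceeded twice the
hysteresis (the attempt floor); smaller wiggles emit nothing. An open
repetition at stream end is closed and evaluated, so aborted sessions keep
their partial counters.

Auto thresholds: `D_min = (L_Thigh + R_Thigh)/6`,
`H_min = 0.75 · (L_Shin + R_Shin)/2`, elbow-lift target = per-arm ratio
(default 0.7) times the arm length — all average difficulty, overridable
per side where the platform allows it.

## Counters and metrics

Per-side success counters freeze at the target N (default 10), freezing
that side's failure counter with them; completion requires every relevant
success counter to equal N. All reported averages (`⟨D⟩/D_min·100%`,
`⟨H⟩/arm·100%`, `⟨H⟩/shin·100%`, circularity) run over *counted successful*
repetitions only, so injected failures leave them unchanged.

If a required joint is inferred for more than 15 consecutive frames the
engine pauses — the stream is split and no events are emitted across the
gap (logged as a warning); shorter inferred runs are used as-is, since the
sensor SDK estimates those positions from the tracked joints.

## Synthetic motion generator

The generator emulates the five movement patterns on a template body
(thigh 0.45 m, shin 0.40 m, upper arm 0.30 m, forearm 0.27 m) with a 1 s
stationary calibration preamble, 3.2 s per repetition and 0.5 s rests.
3.2 s = 96 frames at 30 Hz was chosen so the frame grid divides the circle
into multiples of four: quadrant extremes (top/bottom/front/back) land
exactly on sampled frames and analytic extents are attained by the discrete
signal. Raised-cosine profiles place squat/lift/kick amplitude peaks exactly
on a frame. Wrist circles are constructed on a sphere around the shoulder,
so perfect circles lie exactly in planes x = const while segment lengths
stay constant to machine precision (< 1 mm is asserted in tests); bent-arm
and out-of-reach variants use a two-link inverse-kinematics step.

Defaults encode the study conditions: 10 repetitions per side, circle
radius 0.15 m, squat depth 0.18 m (1.2 × the template's `D_min`), lift
fraction 0.75 (against the 0.7 target), kick fraction 0.825 (1.1 × the
0.75 threshold). Imperfect executions are parameterized per side: partial
circles (trace-and-retrace), elliptical radii, bent arms, tilted forearms,
shallow depths, phase lag between wrists, arbitrary leg order.

The noise model adds isotropic Gaussian jitter per joint per frame,
a fixed-direction sinusoidal tremor (default 5 Hz, the 4–6 Hz resting-tremor
band) on hands and wrists, and random tracked→inferred state flips — all
driven by one seed. What the generator does **not** emulate: soft-tissue
and clothing artifacts, correlated or burst-like tracking errors,
biomechanically coupled whole-body sway, bradykinetic slowing within a
session, or occlusion geometry. Passing tests therefore demonstrate the
correctness of the assessment logic under the stated noise model, not
clinical performance on real patient recordings.

## Numerical notes and limitations

* The 5-frame smoothing filter attenuates a 3.2 s raised-cosine amplitude
  peak by ≈ 0.24% and a circle radius by ≈ 0.43%; counter recovery is exact
  and metric recovery is asserted to 1% in the tests.
* The circularity of the *first* repetition of a set can clip an extreme
  (detection begins mid-quadrant); steady-state repetitions span exactly one
  circle. Over a 10-repetition set the aggregate circularity of perfect
  circles comes out at 1.000–1.003.
* "Half a circle" is operationalized as two same-direction quadrant
  transitions; the platform's description does not define it numerically.
* Exercise 3 does not enforce bilateral unison (only the broomstick exercise
  specifies in-phase movement); seated posture in exercises 4–5 is trusted,
  not verified.
* Comparisons at exact threshold equality follow the documented strict/
  inclusive rules; callers should not rely on float equality at thresholds.
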