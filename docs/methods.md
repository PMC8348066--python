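# Methods

This note documents the models, numerical choices and known limitations of
`stsfatigue`. Everything stated here is computed by the package's test suite
or by `scripts/acceptance.py`; no external result is quoted.

## Protocol model

A session is a timed sit-to-stand (STS) test: the participant sits down and
stands up from a chair as fast as possible, nominally for 120 s, reporting
perceived exertion on the Borg CR10 scale (0–10) every 30 s. The test stops
early if the heart rate exceeds 90% of the age-predicted maximum
(MHR = 206.9 − 0.67·age, the Tanaka estimate for healthy adults) or a Borg
value of 10 is reported. Recording conventions: depth-camera frame with X
lateral, Y vertical up, Z along the camera axis, metres; skeleton at a
nominal 30 Hz; heart rate at 1 Hz; t = 0 at the start command.

## Cycle segmentation

Standing/sitting events are maxima/minima of the mean-subtracted mid-hip
height. Detection parameters, both configurable:

* `min_separation` (default **0.5 s**): same-kind events closer than this
  are merged, keeping the more extreme one (greedy by extremity, ties to the
  earlier event). A human cannot complete an STS phase faster than this.
* `min_prominence_fraction` (default **0.2**): an event must depart from the
  signal mean by at least this fraction of the signal's standard deviation.
  The threshold is applied to the excursion from the mean rather than to a
  topographic peak prominence: it serves purely as a flat-signal/noise
  guard, and an excursion criterion — unlike prominence — is not distorted
  when a peak sits near the start or end of the series. True sit/stand
  extrema lie roughly one SD from the mean and always pass.

Degenerate inputs: a flat signal (or one where nothing passes the
threshold) yields an empty event list with a warning, not an exception. Flat
plateaus of equal samples are reported at the plateau centre, which keeps
phase durations unbiased. Alternation is enforced by collapsing same-kind
runs to their most extreme member. Recording gaps longer than 0.2 s split
the signal; detection runs per contiguous block and event values are
re-expressed against the whole-signal mean.

Cycles are consecutive (max, min, max) triples; unmatched leading/trailing
extrema are dropped, a deliberate choice since partial boundary cycles have
no defined phase structure. A cycle's representative time for downstream
nearest-cycle selection is its midpoint (start + end)/2; the protocol does
not define a representative time, and the midpoint is unbiased with respect
to the two phases. The stand-to-stand duration is computed as the sum of the
two phase durations so that F1 = F2 + F3 holds to machine precision.

## Features

32 per-cycle features: durations (s), marker ranges (m), peak linear
velocities (m/s), joint-angle ranges (degrees) and peak angular velocities
(degrees/s). Conventions and choices:

* Derivatives are central finite differences (one-sided at the series ends),
  exact for linear signals and within sinc(ω/2f) of analytic values for
  band-limited ones (≈0.7% at 4 Hz content sampled at 30 Hz). No smoothing
  is applied by default; an optional moving-average pre-filter
  (`smooth_window`, in samples) is available for noisy recordings.
* "Min velocity" features take the minimum of the derivative, "max velocity"
  features the maximum, uniformly — including the hip and shoulder depth
  features whose verbal descriptions are sometimes garbled in the
  literature this pipeline follows. Angular-velocity features are in
  degrees/s even where source material prints bare degrees.
* Relative joint rotations (hip: mid-hip → knee orientation; spine:
  shoulder-centre → mid-hip orientation) are decomposed with the intrinsic
  X–Y–Z Tait–Bryan sequence; the X angle is flexo-extension, the Z angle
  abduction-adduction. The sequence is configurable in principle (the
  tracker SDK's convention is not universal); near gimbal lock
  (|Y angle| = 90°) the convention-resolved value is returned with a
  warning. Both left and right relative rotations are computed and averaged
  for the starred features F10–F21.
* Windowing: ranges of angle signals and minimum angular velocities use the
  sit-to-stand phase, maximum angular velocities the stand-to-sit phase,
  marker ranges the full stand-to-stand cycle. Windows are
  endpoint-inclusive; a cycle whose window falls outside the recorded series
  is skipped with a warning.

## Dataset construction

Borg interpolation is piecewise linear through (0, 0) — the participant
starts unfatigued — and the reports, evaluated every 10 s; a 120 s session
gives 13 grid values. Aggregation to each grid timepoint uses the k = 5
nearest cycles by midpoint (and 5 nearest 1 Hz heart-rate samples), ties
toward the earlier cycle. Assignment is greedy in chronological order
without cycle reuse; only the last labeled timepoint may reuse cycles, since
the cycle rate is lowest at the end of the test. The t = 0 aggregate is the
normalization baseline (Eq. f_i/f_0 per feature) and produces no
observation; neither does the final grid value. Fractional interpolated Borg
values are labeled by round-half-up and integer banding (LF ≤ 3.5 < MF ≤
6.5 < HF).

The heart-rate baseline defaults to the t = 0 aggregate (`hr_baseline="t0"`)
so F33 is normalized exactly like F1–F32; `"resting"` substitutes the
pre-test resting heart rate for users who prefer a physiological anchor.
Early-terminated sessions are supported: the grid runs to the session
duration and yields (grid length − 2) registers.

## Models and evaluation

Family defaults: RF 60 trees; SVM with RBF kernel, C = 2, balanced class
weights; MLP with layers (100, 20, 100), relu, adam, α = 0.05, adaptive
learning rate, ≤1000 iterations; logistic regression with lbfgs and
C = 1000; KNN with 12 neighbours (27 is a documented alternative from the
same source material). Features are near-1 ratios after normalization, so no
standardization is applied by default; `standardize=True` inserts z-scoring
for the scale-sensitive families.

Evaluation is seeded k-fold cross-validation, default k = 6 (a 660-register
dataset gives folds of 110). Register-level fold assignment is the default;
it leaks subjects across folds, so `group_by_participant=True` offers
subject-wise folds. Confusion matrices store predictions on rows and true
labels on columns. Macro averages over the three classes are the headline
precision/recall/F numbers; micro averages (which collapse to accuracy for
single-label multiclass) are also emitted. A class never predicted in a fold
gets precision 0 with a warning; a training fold missing a class is skipped
and flagged. RF feature importances are impurity-based, averaged over folds
and renormalized to sum to 1.

## Synthetic generator

`synthgen` emulates the study conditions with exact ground truth:

* **Kinematics.** A raised-cosine sit/stand waveform u(t) (1 standing, 0
  sitting) with independent stand-to-sit (45% of the cycle by default) and
  sit-to-stand phases — a pure sinusoid could not express F2 ≠ F3. Event
  times snap to the 30 Hz sampling grid so injected phase durations are
  exactly representable; recovered durations are then within one sample
  interval of truth. Marker positions follow u(t): mid-hip and shoulder
  trajectories directly, leg markers by forward kinematics from shank-tilt
  and knee-vertex-angle waveforms (shank 0.42 m, thigh 0.44 m). Orientations
  are composed as X-then-Z rotations so the relative-rotation features
  recover the injected angle waveforms exactly.
* **Fatigue envelope.** Effects accrue as √((t − 7 s)/(T − 10 − 7 s)),
  clipped to [0, 1]: zero during the first few baseline cycles, saturated by
  the last labeled timepoint. The square-root shape front-loads fatigue, as
  a maximal-effort bout does, and places the class means of the normalized
  stand-to-stand time near 1.15/1.30/1.41 for LF/MF/HF under the default
  Borg schedule (measured on the default 60-participant cohort, seed 7). Default final/initial ratios: stand-to-stand time 1.45,
  shoulder depth range 0.80, heart rate 1.60, with smaller drifts on the
  remaining families; peak-velocity effects emerge from the amplitude and
  period changes rather than separate dials.
* **Heart rate.** A saturating ramp r + Δ(1 − e^(−t/τ)), τ = 45 s, with Δ
  solved in closed form so the final/initial aggregate ratio equals the
  target exactly, capped below 0.9·MHR (the termination ceiling is never
  crossed in a complete session).
* **Borg.** Reports every 30 s from a monotone schedule reaching 10 at
  120 s, with ±1 per-participant jitter on intermediate reports.
* **Cohorts.** Sex-balanced; demographics uniform within mean ± 2 SD of the
  study population (age ≈ 18–26, weight ≈ 48–79 kg, height ≈ 148–189 cm);
  base cycle period 1.25 s ± 12% and effect sizes ± 20% between
  participants. Noise is independent Gaussian jitter: 4 mm on marker
  positions, 1 bpm on heart rate, 0.3° on orientations.

What the generator does **not** model: tracker occlusion and autocorrelated
tracking error, left/right asymmetry, within-session pauses or posture
resets, HR variability structure, and non-monotone perceived exertion.
Passing tests therefore demonstrate the pipeline's correctness and its
sensitivity under idealized-but-noisy recordings, not clinical performance
on real depth-camera data.

## Problem sizes used in tests

The default verification cohort is 60 participants × 120 s (660 registers,
matching the protocol arithmetic); parameter-recovery checks use a noiseless
6-participant cohort and a 20-participant cohort with between-subject
variability but no measurement noise; the permutation null uses 20 seeds.
Oracle-equivalence checks run 100 random smooth signals (length ≤ 300) and
100 random rotations.

## Known limitations

* The Euler-sequence convention for "X-axis angle" is an assumption; real
  tracker data may require a different sequence (it is isolated in
  `relative_axis_angle`).
* Register-level cross-validation overstates generalization to unseen
  subjects; use `group_by_participant=True` for subject-wise estimates.
* The figshare deposit of the original study is not parsed: its internal
  format is undocumented. Sessions enter via the documented bundle schema.
* Classification accuracy on synthetic cohorts reflects the injected effect
  sizes; it is a pipeline property check, not a reproduction of any field
  study's accuracy.
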