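# Methods

`stairgaze` reimplements, as a tested pipeline, the analysis of where people
look while walking down and up two staircases (12 and 9 steps, each step
with a 30 cm run and 16 cm rise, i.e. about 28° steep) recorded with a
head-mounted eye tracker (gaze at a nominal 200 Hz in head-fixed degrees of
visual angle) and its inertial measurement unit (vertical head
displacement).  Two instruction groups are compared: one told that walking
the stairs *is* the task (stairs-relevant) and one for whom the stairs are
merely on the way to a different task (stairs-irrelevant).

## Event detection

**Saccades.**  After removing blink intervals, gaze velocity is a two-point
finite difference on consecutive valid samples (no pre-smoothing — the
detector's definition names no filter, and the consistency criterion below
does the denoising).  A stretch of recording belongs to a saccade when the dot
product of the velocity on consecutive samples exceeds 10 times the median
absolute value of that dot product over the whole session (one walk = one
session; the median is taken after blink removal).  The dot product is
large only for motion that is fast *and* keeps its direction across
samples, which separates saccades from white fixational jitter whose
successive velocity vectors point in independent directions.

Numerical choices:

* A candidate needs at least 2 consecutive supra-threshold dot products
  (≥ 4 samples of consistent motion), so a single noisy sample pair cannot
  fire the detector.  Configurable (`DetectorConfig.min_consistent_samples`).
* Candidate boundaries are refined outward to the nearest local speed
  minimum, stopping as soon as the squared speed falls to twice the session
  median dot product (the fixational baseline).  Without this, the
  supra-threshold core clips the slow minimum-jerk tails and amplitudes are
  underestimated by 1–3 %, which matters right at the 3° floor.
* Amplitude is the planar angular distance between the gaze positions at
  the refined start and end (small-angle regime, consistent with
  degrees-of-visual-angle coordinates).  Candidates under 3° are discarded.
* Saccades closer than 100 ms: the slower one (lower peak speed) is removed,
  iterating on the earliest offending pair until all gaps are legal; on
  equal peak speeds the later event goes.  The pruning is a fixed point —
  re-running it changes nothing (tested).
* A session whose median dot product is zero (perfectly static gaze) yields
  no saccades and a warning rather than dividing by zero.

Saccade direction is head-fixed with 0° upward in the scene camera and 90°
rightward; direction histograms use 40 half-open bins of 9°, optionally
stratified by minimum-amplitude classes.

**Foot placements.**  While climbing, the head is lowest once per stride,
at the moment the foot is planted.  The head-height trace is
mean-subtracted and smoothed with a moving average of a quarter stride
period; cycles are delimited by downward zero crossings and the placement
is the per-cycle minimum.  Cycles shorter than 0.4 stride periods or
shallower than 25 % of the robust signal amplitude (95th percentile of
|z|) are rejected as noise.  Placements are split into staircase
traversals at gaps longer than 1.75 stride periods and numbered
sequentially — step 1 is always the first step the walker meets, so step
numbering is direction-relative throughout the package.  Time on stairs is
the sum over the two staircases of (last − first placement); it is missing
if either staircase has fewer than two placements.

**Analysis window.**  Gaze counts toward a staircase only from 2 s before
its first foot placement until its last one (closed on both ends; the
paper states no endpoint convention and closed intervals avoid dropping
boundary samples).  Saccade metrics start at the first step fixation
inside that window.

## Fixation coding

Frame-level area-of-interest labels (nominal 30 Hz) stand in for the
study's manual video coding; the label stream is `stair<i>_step<k>`,
`elsewhere` or `none`.  A step is fixated when its label persists for at
least two frames (about 66 ms).  Sub-threshold runs are discarded and
adjacent same-label events then merge, so a one-frame intrusion does not
split a fixation (`strict_breaks=True` gives the alternative reading in
which it does).  All non-step fixations pool under a single `elsewhere`
label; step fixations belonging to the other staircase of the walk count
as elsewhere for the staircase being analysed.  Each staircase's sequence
is trimmed to run from the first to the last fixation on one of its steps;
events straddling the window boundary are kept when at least two of their
frames fall inside.

## Sequence statistics

A transition is an ordered pair of successively fixated steps; its offset
is (later − earlier step number), positive toward travel.  It is *direct*
with no intervening elsewhere fixation, *indirect* otherwise (offset 0 is
then possible: away and back to the same step).  The indirect share is
indirect / all transitions, reported both pooled over a group×direction
cell (default, and what the script reports) and as the mean of
per-participant shares.  The fraction of fixated steps is distinct fixated
steps over step count, averaged across the two staircases; steps fixated
during the 2 s pre-window count.

## Group statistics

The three dependent variables — fraction of fixated steps, mean saccade
amplitude (mean of the two per-staircase means), time on stairs — enter a
2×2 mixed ANOVA with Group between subjects and Direction
(descending/ascending) within, computed through `pingouin.mixed_anova`
with partial eta squared = SS_effect / (SS_effect + SS_error).  Only
complete cases enter (participants with both directions), which is what
makes the between-effect denominator df equal n_complete − 2 (29 for
17 + 14).  With two within levels no sphericity correction applies, and,
by design no multiple-testing correction is made across the three
variables (each answers its own question).  Degenerate inputs: a table with no variance
at all returns zero F; zero error variance with non-zero effects raises a
flagged error.  Correlations (time on stairs vs fraction fixated, per
direction, across groups) are Pearson product-moment.  A diagnostic
compares the per-session detector medians between groups (Welch t), since
a systematic group difference there would confound the adaptive threshold.

## Synthetic-data generator

The generator produces walks with the statistical structure the analysis
assumes, plus complete ground truth, and its defaults are the study
conditions the package is validated under:

* **Cohort**: 18 stairs-relevant / 16 stairs-irrelevant participants, each
  walking both directions.  Per-step fixation probability 0.80 vs 0.60
  (≈80 % vs ≈60 % of steps fixated), indirect-shift probability 0.09 vs
  0.23 (9 % vs 23 % indirect shares), mean saccade amplitude 4.5° vs 6.0°
  with sd 1° (the emulated regime has smaller saccades for the
  stairs-relevant group; the absolute values are a design choice, as no
  amplitudes are specified numerically), elsewhere-shift direction bias
  toward the open side of the staircase (left when descending, mirrored
  when ascending) with higher circular concentration for the
  stairs-irrelevant group.
* **Sequences**: each step is independently fixated with probability
  `p_fixate_step` and the fixated steps are visited in travel order, so
  the expected fraction of fixated steps is exactly `p_fixate_step` and
  Direct offsets beyond +1 arise from skipped steps.  Backward glances at
  already fixated steps occur at the rate of the negative mass of
  `step_offset_weights` (mass at +1 means "continue forward"; a weight at
  0 is rejected — same-step returns belong to the indirect mechanism).
  Each transition is independently indirect with probability `p_indirect`;
  with probability `p_indirect_return_same` (default 0.35) an indirect
  shift returns to the same step before continuing, and the continuation
  pair is re-decided independently, which leaves the expected indirect
  share exactly `p_indirect` while producing the offset-0 peak of the
  Indirect distribution.
* **Signals**: while fixating a step the gaze tracks it as the walker
  advances (the step column's elevation moves at roughly one
  inter-step spacing per stride), so even noise-free fixations drift
  slowly and the detector's session median stays strictly positive.
  Saccades follow a minimum-jerk profile with duration 20 ms + 2 ms per
  degree.  Step regions are rectangles (±2° azimuth, about ±2° elevation)
  around moving centres spaced one mean saccade amplitude apart in
  elevation; within-fixation scatter and truncated (±3σ) white measurement
  noise are kept inside the rectangle so frame labels and gaze geometry
  never disagree.  The head trace oscillates once per stride (phase locked
  to the jittered placement times) only while on a staircase and is flat
  in between; strides are 0.55 s with 4 % per-stride jitter, 6 %
  between-participant and 5 % per-walk pace variability, and ascending is
  slower by a factor 1.20 (relevant) / 1.32 (irrelevant) — values chosen so
  the simulated time-on-stairs ANOVA shows the emulated pattern (direction
  effect and interaction present, no group effect); no numeric walking
  times are specified, so the absolute times are a design choice.  Blinks
  are Poisson at 0.1 Hz, 150 ms each.
* **Reproducibility**: per-recording random streams derive from the master
  seed through `numpy` `SeedSequence` spawn keys, so cohorts are identical
  across runs and stable under reordering.

What the generator does **not** emulate: pixel-space video and camera
calibration (it emits degrees directly), eye-tracker noise spectra beyond
white jitter, glissades/pursuit, head-free gaze-in-world geometry, head
bobbing during level walking (the flat inter-staircase segments are what
lets placement counts be checked exactly), and any imperfection of the
human coder — frame labels are truth up to the two-frame rule.  Passing
recovery tests therefore shows the pipeline is faithful to its own rules
on data obeying its assumptions, not that those rules are optimal for real
recordings.

## Problem sizes used in the test suite

Recovery tests use noise-free walks (8 walks across groups × directions ×
seeds); parameter recovery uses 30 participants per group (120 walks);
the power check runs 200 replicates of a 17 + 15 complete-case cohort and
expects the Group effect on fraction fixated at α = 0.05 in at least 80 %
of them; detector-vs-reference equivalence uses 100 random traces of up to
2000 samples.  The acceptance script simulates one full study-sized cohort
(18 + 16, both directions, three exclusions applied) and reports the
pipeline's headline numbers.

## Known limitations

* The mixed ANOVA uses the classical weighted-means decomposition (what
  `pingouin` computes); with unbalanced groups other weighting conventions
  exist and give slightly different sums of squares.
* `GeneratorParams` carries one `p_indirect` per group, so the
  stairs-irrelevant group uses its descending indirect share (23 %) in
  both directions, although the emulated regime's ascending share is a
  little lower (18 %).
* The gait detector assumes one head-height minimum per step and no
  oscillation off the stairs; on real level-walking segments it would need
  an amplitude gate tuned to stair bobbing.
* Whether "the slower of the two" saccades means lower peak speed or
  smaller amplitude is ambiguous in prose; peak speed is the default and
  the refractory pruner is the single place that would change.
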