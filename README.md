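# stairgaze

Where do people look when they walk down a staircase — and does it change
when they know the staircase is the point of the experiment?  `stairgaze`
is an analysis pipeline for mobile eye-tracking recordings of stair
walking.  It takes per-walk gaze traces (head-fixed azimuth/elevation in
degrees, ~200 Hz), blink intervals, vertical head displacement from the
tracker's IMU, and a per-scene-frame area-of-interest label stream
(~30 Hz), and produces per-participant gaze statistics and group-level
inference for a two-group (stairs-relevant vs stairs-irrelevant), two-
direction (descending vs ascending) design.

The pipeline implements, as reusable and tested code:

* **Saccade detection** with a session-adaptive threshold: a stretch of
  recording is saccadic when the dot product of gaze velocity on
  consecutive samples, **v**ᵢ·**v**ᵢ₊₁, exceeds 10× the session median of
  |**v**ᵢ·**v**ᵢ₊₁| — fast *and* directionally consistent motion.  A 3°
  amplitude floor and a 100 ms refractory rule (the slower of two close
  saccades is removed) follow.  Directions are binned into 40 × 9° bins
  (0° = up in the scene camera, 90° = right).
* **Gait events** from head height: the head's lowest position in each
  stride marks a stable foot placement; placements delimit each
  staircase's span, the time on stairs, and the analysis window (gaze
  counts from 2 s before the first placement to the last).
* **Fixation coding** from frame labels: a step is fixated when its label
  persists ≥ 2 frames (~66 ms); same-step fixations merge; everything off
  the steps pools as "elsewhere".
* **Sequence statistics**: Direct/Indirect step-transition offset
  histograms, the indirect share, and the fraction of fixated steps
  (distinct steps / step count, averaged over the two staircases).
* **Group statistics**: 2×2 mixed ANOVA (Group between × Direction
  within, via pingouin) with partial eta squared
  η²ₚ = SS_effect / (SS_effect + SS_error), Pearson correlations, and
  exclusion bookkeeping.
* A **synthetic-walk generator** that emulates the recordings (two
  staircases of 12 and 9 steps, run 30 cm, rise 16 cm ⇒ ≈28° steep) with
  full ground truth — true saccades, fixation sequences, foot placements —
  so every stage is testable end-to-end without any real data.

## Worked example

Simulate a default cohort (18 + 16 participants, both directions), run the
whole pipeline and print the cell means:

```sh
stairgaze report --out out/ --seed 1
```

```
stairs_irrelevant/ascending:
  fraction_fixated: 0.6334876543209877
  mean_amp_deg: 10.472392898202772
  time_on_stairs_s: 13.892777777777777
stairs_irrelevant/descending:
  fraction_fixated: 0.5679012345679013
  mean_amp_deg: 12.618594016440088
  time_on_stairs_s: 10.347222222222221
stairs_relevant/ascending:
  fraction_fixated: 0.8202160493827161
  mean_amp_deg: 6.072397526203869
  time_on_stairs_s: 12.522222222222222
stairs_relevant/descending:
  fraction_fixated: 0.845679012345679
  mean_amp_deg: 6.091669041223392
  time_on_stairs_s: 10.394722222222223
```

Participants told the stairs are the task fixate ~82–85 % of the steps
with ~6° saccades; participants for whom the stairs are incidental fixate
~57–63 % with larger saccades, and everyone is slower walking up than
down.  `out/metrics.json` holds the inference; for this run the Group
effect on the fraction of fixated steps is F(1, 34) = 54.6, p < 0.001,
η²ₚ = 0.62.  `out/summary.csv` has one row per participant × direction and
`out/transition_histograms.csv` the pooled Direct/Indirect offset counts.

The same stages are available piecemeal (`stairgaze simulate`,
`detect-saccades`, `gait`, `code-fixations`, `summarize`, `anova`) and as
a library:

```python
import stairgaze as sg

walks = sg.generate_cohort(sg.default_group_params(), n_per_group=4, seed=0)
result = sg.analyze_recording(walks[0][0])
print(result.summary.fraction_fixated, len(result.saccades_all))
```

Every analysis constant (10× threshold, 3° floor, 100 ms interval, 2-frame
minimum, 2 s window, 9° bins, α = 0.05) lives in `RunConfig`, is
overridable from YAML/JSON, and is echoed (with a config hash) into every
output.

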