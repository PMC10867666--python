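"""Fixation coding from frame-level area-of-interest labels.

Reproduces the study's manual coding rules on a machine-readable label
stream: a step counts as fixated when the same step label persists for at
least two scene frames (about 66 ms); sequential fixations on the same step
merge under one step number; all non-step fixations pool under a single
``elsewhere`` label.  The result is, per walk, a sequence of fixated steps
interleaved with periods of looking elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traces import ELSEWHERE, NONE_LABEL, FrameLabels, StepRef, parse_label

MIN_FRAMES = 2


@dataclass
class FixationEvent:
    """A coded fixation: a step (StepRef) or ``elsewhere``."""

    label: StepRef | str
    start_s: float
    end_s: float
    n_frames: int
    frame_t: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def is_step(self) -> bool:
        return isinstance(self.label, StepRef)


@dataclass
class GazeSequence:
    """Time-ordered fixation events of one staircase's analysis window,
    trimmed to run from the first to the last step fixation."""

    events: list[FixationEvent]
    staircase: int
    window: tuple[float, float]

    @property
    def step_events(self) -> list[FixationEvent]:
        return [e for e in self.events if e.is_step]

    def distinct_steps(self) -> set[int]:
        return {e.label.step for e in self.step_events}  # type: ignore[union-attr]


def _runs(labels: np.ndarray) -> list[tuple[int, int, str]]:
    """Run-length encode: (start index, length, label)."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start, i - start, str(labels[start])))
            start = i
    return out


def label_fixations(
    frames: FrameLabels,
    min_frames: int = MIN_FRAMES,
    strict_breaks: bool = False,
) -> list[FixationEvent]:
    """Turn the frame label stream into merged fixation events.

    Maximal runs of one label lasting at least ``min_frames`` frames become
    events; shorter runs are discarded.  ``none`` frames (no stable gaze,
    e.g. during saccades) never form events.  After discarding, adjacent
    events with the same label merge — so a one-frame intrusion inside a
    step fixation does not split it.  With ``strict_breaks`` a discarded
    intrusion does break the merge (the alternative reading of the rule).
    """
    if len(frames) == 0:
        return []
    pooled = np.array(
        [
            str(lab) if isinstance(parse_label(str(lab)), StepRef) or lab == NONE_LABEL
            else ELSEWHERE
            for lab in frames.labels
        ],
        dtype=object,
    )
    kept: list[tuple[int, int, str] | None] = []
    for start, length, lab in _runs(pooled):
        if lab == NONE_LABEL:
            if strict_breaks and length >= min_frames:
                kept.append(None)
            continue
        if length < min_frames:
            if strict_breaks:
                kept.append(None)
            continue
        kept.append((start, length, lab))

    events: list[FixationEvent] = []
    for item in kept:
        if item is None:
            events.append(None)  # type: ignore[arg-type]
            continue
        start, length, lab = item
        t = frames.t[start : start + length]
        if events and events[-1] is not None and str(events[-1].label) == lab:
            prev = events[-1]
            prev.end_s = float(t[-1])
            prev.n_frames += length
            prev.frame_t = np.concatenate([prev.frame_t, t])
        else:
            events.append(
                FixationEvent(parse_label(lab), float(t[0]), float(t[-1]), length, t.copy())
            )
    return [e for e in events if e is not None]


def restrict_to_staircase(
    events: list[FixationEvent],
    window: tuple[float, float],
    staircase: int,
    min_frames_inside: int = 2,
) -> GazeSequence:
    """Restrict coded fixations to one staircase's analysis window.

    Events with at least ``min_frames_inside`` frames inside the closed
    window are kept; step fixations belonging to the *other* staircase are
    treated as looking elsewhere.  The sequence is trimmed to start at the
    first and end at the last fixation on a step of this staircase, dropping
    elsewhere fixations outside that span; an empty sequence is legal.
    """
    w0, w1 = window
    inside: list[FixationEvent] = []
    for e in events:
        n_in = int(np.count_nonzero((e.frame_t >= w0) & (e.frame_t <= w1)))
        if n_in < min_frames_inside:
            continue
        label = e.label
        if isinstance(label, StepRef) and label.stair != staircase:
            label = ELSEWHERE
        inside.append(FixationEvent(label, e.start_s, e.end_s, e.n_frames, e.frame_t))

    # relabelling may have created adjacent elsewhere events: merge them
    merged: list[FixationEvent] = []
    for e in inside:
        if merged and str(merged[-1].label) == str(e.label):
            merged[-1].end_s = e.end_s
            merged[-1].n_frames += e.n_frames
            merged[-1].frame_t = np.concatenate([merged[-1].frame_t, e.frame_t])
        else:
            merged.append(e)

    step_idx = [i for i, e in enumerate(merged) if e.is_step]
    if not step_idx:
        return GazeSequence([], staircase, window)
    return GazeSequence(merged[step_idx[0] : step_idx[-1] + 1], staircase, window)
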