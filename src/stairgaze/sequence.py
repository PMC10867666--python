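"""Gaze-sequence statistics: step-transition distributions, the share of
indirect gaze shifts, and the fraction of fixated steps.

A transition is the ordered pair of two successively fixated steps.  Its
offset is (later step number - earlier step number) in direction-relative
numbering, so +1 always means the next step in the direction of travel.  A
transition is *direct* when no elsewhere fixation intervenes and *indirect*
otherwise; an indirect transition may have offset 0 (gaze shifts away from
a step and back to the same step).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .coding import GazeSequence
from .geometry import StaircaseGeometry


@dataclass
class TransitionHistogram:
    direct: Counter = field(default_factory=Counter)
    indirect: Counter = field(default_factory=Counter)

    @property
    def n_transitions(self) -> int:
        return sum(self.direct.values()) + sum(self.indirect.values())

    def __add__(self, other: "TransitionHistogram") -> "TransitionHistogram":
        return TransitionHistogram(
            self.direct + other.direct, self.indirect + other.indirect
        )


@dataclass
class ParticipantSummary:
    """Per participant x direction dependent variables."""

    participant: str
    group: str
    direction: str
    fraction_fixated: float
    mean_amp_deg: float
    time_on_stairs_s: float
    indirect_share: float
    transitions: TransitionHistogram = field(default_factory=TransitionHistogram)
    m_session: float = float("nan")


def transition_distribution(seq: GazeSequence) -> TransitionHistogram:
    """Count direct/indirect step offsets over one staircase's sequence."""
    hist = TransitionHistogram()
    prev_step: int | None = None
    elsewhere_between = False
    for e in seq.events:
        if e.is_step:
            step = e.label.step  # type: ignore[union-attr]
            if prev_step is not None:
                offset = step - prev_step
                (hist.indirect if elsewhere_between else hist.direct)[offset] += 1
            prev_step = step
            elsewhere_between = False
        else:
            elsewhere_between = True
    return hist


def indirect_share(hist: TransitionHistogram) -> float:
    """Indirect transitions as a fraction of all transitions; NaN when the
    sequence holds no transitions at all."""
    total = hist.n_transitions
    if total == 0:
        return float("nan")
    return sum(hist.indirect.values()) / total


def fraction_fixated(
    seqs: tuple[GazeSequence, GazeSequence],
    staircases: tuple[StaircaseGeometry, StaircaseGeometry],
) -> float:
    """Distinct fixated steps over total steps, averaged across the two
    staircases.  Steps fixated in the 2 s pre-staircase window are already in
    the sequences; an empty sequence contributes 0."""
    fracs = []
    for seq, geo in zip(seqs, staircases):
        fracs.append(len(seq.distinct_steps()) / geo.n_steps)
    return float(np.mean(fracs))
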