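"""Staircase geometry.

The study site has two long staircases (12 and 9 steps); every step has a
run of 30 cm and a rise of 16 cm, i.e. a steepness of atan(16/30) ~ 28 deg.
Step numbering throughout the package is *direction-relative*: step 1 is the
first step the walker meets, regardless of whether they ascend or descend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


class InvalidGeometryError(ValueError):
    """Raised for non-positive staircase dimensions."""


@dataclass(frozen=True)
class StaircaseGeometry:
    """A flight of identical steps.

    Attributes
    ----------
    n_steps : int
        Number of steps (>= 1).
    run_cm, rise_cm : float
        Tread depth and riser height of each step, in centimetres.
    steepness_deg : float
        Inclination angle atan(rise/run) in degrees; derived, in (0, 90).
    """

    n_steps: int
    run_cm: float
    rise_cm: float
    steepness_deg: float

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise InvalidGeometryError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.run_cm <= 0 or self.rise_cm <= 0:
            raise InvalidGeometryError(
                f"run/rise must be positive, got run={self.run_cm}, rise={self.rise_cm}"
            )
        if not 0.0 < self.steepness_deg < 90.0:
            raise InvalidGeometryError(f"steepness out of (0, 90): {self.steepness_deg}")


def make_staircase(n_steps: int, run_cm: float, rise_cm: float) -> StaircaseGeometry:
    """Build a staircase, computing steepness from rise over run."""
    if int(n_steps) != n_steps or n_steps < 1:
        raise InvalidGeometryError(f"n_steps must be a positive integer, got {n_steps!r}")
    if run_cm <= 0 or rise_cm <= 0:
        raise InvalidGeometryError(
            f"run/rise must be positive, got run={run_cm}, rise={rise_cm}"
        )
    steep = math.degrees(math.atan2(rise_cm, run_cm))
    return StaircaseGeometry(int(n_steps), float(run_cm), float(rise_cm), steep)


#: The two long staircases of the study building, in *descending* walk order.
#: Ascending walkers meet them in reverse order.
LONG_STAIRCASES_DESCENDING = (
    make_staircase(12, 30.0, 16.0),
    make_staircase(9, 30.0, 16.0),
)


def staircases_for_direction(direction: str) -> tuple[StaircaseGeometry, StaircaseGeometry]:
    """Staircase pair in the order met when walking ``direction``."""
    if direction == "descending":
        return LONG_STAIRCASES_DESCENDING
    if direction == "ascending":
        return tuple(reversed(LONG_STAIRCASES_DESCENDING))  # type: ignore[return-value]
    raise ValueError(f"unknown direction {direction!r}")
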