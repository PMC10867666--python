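"""Raw signal containers: gaze, head (IMU) and scene-frame label streams.

Gaze is expressed in head-fixed degrees of visual angle (azimuth positive
rightward, elevation positive upward), sampled nominally at 200 Hz.  Scene
frames carry the area-of-interest label stream (nominally 30 Hz) that stands
in for manual video coding: ``stair<i>_step<k>`` (direction-relative step k
of staircase i in walk order), ``elsewhere`` or ``none``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

ELSEWHERE = "elsewhere"
NONE_LABEL = "none"

_STEP_RE = re.compile(r"^stair(\d+)_step(\d+)$")


class StepRef(NamedTuple):
    """A step identified by staircase index (1-based, walk order) and step number."""

    stair: int
    step: int

    def __str__(self) -> str:
        return f"stair{self.stair}_step{self.step}"


def parse_label(label: str) -> StepRef | str:
    """Parse a frame label into a :class:`StepRef`, ``elsewhere`` or ``none``."""
    m = _STEP_RE.match(label)
    if m:
        return StepRef(int(m.group(1)), int(m.group(2)))
    if label in (ELSEWHERE, NONE_LABEL):
        return label
    raise ValueError(f"unknown frame label {label!r}")


def _check_increasing(t: np.ndarray, name: str) -> None:
    if t.ndim != 1:
        raise ValueError(f"{name}: timestamps must be 1-D")
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise ValueError(f"{name}: timestamps not strictly increasing at row {bad}")


@dataclass
class GazeTrace:
    """Timestamped 2-D gaze directions with a per-sample validity flag.

    ``valid`` is False inside blinks or otherwise removed spans; velocity is
    never computed across an invalid gap.
    """

    t: np.ndarray
    az: np.ndarray
    el: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        self.el = np.asarray(self.el, dtype=float)
        if self.valid is None:
            self.valid = np.ones(len(self.t), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.t) == len(self.az) == len(self.el) == len(self.valid)):
            raise ValueError("gaze arrays must share one length")
        _check_increasing(self.t, "gaze")
        if np.any(~np.isfinite(self.az[self.valid])) or np.any(
            ~np.isfinite(self.el[self.valid])
        ):
            raise ValueError("gaze: non-finite az/el on valid samples")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class ImuTrace:
    """Vertical head displacement over time (arbitrary consistent length unit)."""

    t: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if len(self.t) != len(self.z):
            raise ValueError("imu arrays must share one length")
        _check_increasing(self.t, "imu")
        if np.any(~np.isfinite(self.z)):
            raise ValueError("imu: non-finite displacement")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class FrameLabels:
    """Per-scene-frame area-of-interest labels (the coding input)."""

    t: np.ndarray
    labels: np.ndarray  # array of str

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.t) != len(self.labels):
            raise ValueError("frame arrays must share one length")
        _check_increasing(self.t, "frames")

    def __len__(self) -> int:
        return len(self.t)

    def validate_labels(self, n_steps_by_stair: dict[int, int] | None = None) -> None:
        """Check every label parses; optionally bound step numbers by geometry."""
        for i, lab in enumerate(self.labels):
            ref = parse_label(str(lab))
            if isinstance(ref, StepRef) and n_steps_by_stair is not None:
                n = n_steps_by_stair.get(ref.stair)
                if n is None:
                    raise ValueError(f"frames row {i}: unknown staircase in {lab!r}")
                if not 1 <= ref.step <= n:
                    raise ValueError(
                        f"frames row {i}: step {ref.step} outside 1..{n} in {lab!r}"
                    )
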