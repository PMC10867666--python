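"""Foot-placement detection from vertical head displacement.

While climbing stairs the head bobs once per step; the head's lowest
position within each stride marks the moment the foot is placed stably.
Strides are segmented as cycles of the mean-subtracted, lightly smoothed
displacement signal, and the placement is the per-cycle minimum.

The module also derives each staircase's analysis window: gaze is only
considered from 2 s before the first foot placement until the last one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .traces import ImuTrace

logger = logging.getLogger(__name__)

PRE_WINDOW_S = 2.0


class NoStridesError(ValueError):
    """Raised when the displacement trace contains no stride cycles."""


@dataclass(frozen=True)
class FootPlacement:
    t: float
    staircase: int  # 1-based index in walk order; 0 = unassigned
    step_index: int  # 1-based within the staircase; 0 = unassigned


@dataclass(frozen=True)
class StairInterval:
    """Span from first to last foot placement on one staircase."""

    first_step_t: float
    last_step_t: float

    def __post_init__(self) -> None:
        if self.last_step_t <= self.first_step_t:
            raise ValueError("stair interval must have last > first placement")

    @property
    def window_start_t(self) -> float:
        return self.first_step_t - PRE_WINDOW_S


def _moving_average(z: np.ndarray, win: int) -> np.ndarray:
    if win <= 1:
        return z.copy()
    kernel = np.ones(win) / win
    # reflect-pad so the smoothed signal keeps the trace length
    pad = win // 2
    zp = np.pad(z, pad, mode="edge")
    out = np.convolve(zp, kernel, mode="same")[pad : pad + len(z)]
    return out


def detect_foot_placements(
    imu: ImuTrace,
    expected_stride_period_s: float,
    smooth_window_frac: float = 0.25,
    min_depth_frac: float = 0.25,
) -> list[FootPlacement]:
    """One foot placement per stride cycle of the head-height signal.

    Cycles are delimited by downward zero crossings of the mean-subtracted,
    moving-average-smoothed signal (window = ``smooth_window_frac`` stride
    periods); the placement is the argmin within the cycle.  Cycles shorter
    than 0.4 stride periods or shallower than ``min_depth_frac`` of the
    robust signal amplitude are rejected as noise.
    """
    if expected_stride_period_s <= 0:
        raise ValueError("stride period must be positive")
    if len(imu) < 2 or imu.t[-1] - imu.t[0] < 2 * expected_stride_period_s:
        raise NoStridesError("trace shorter than two stride periods")
    dt = float(np.median(np.diff(imu.t)))
    win = max(1, int(round(smooth_window_frac * expected_stride_period_s / dt)))
    zs = _moving_average(imu.z - np.mean(imu.z), win)
    logger.info("gait: smoothing window %d samples (%.3f s)", win, win * dt)

    # downward zero crossings: positive (or zero) -> strictly negative
    sign = zs < 0
    down = np.flatnonzero(~sign[:-1] & sign[1:])
    if len(down) == 0:
        raise NoStridesError("no stride cycles found (flat or monotonic trace)")
    amp = float(np.percentile(np.abs(zs), 95))
    depth_thr = min_depth_frac * amp
    min_dur = 0.4 * expected_stride_period_s

    bounds = list(down + 1) + [len(zs)]
    placements = []
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        seg = zs[b0:b1]
        if len(seg) == 0:
            continue
        k = int(np.argmin(seg))
        depth = -float(seg[k])
        dur = imu.t[b1 - 1] - imu.t[b0]
        if depth < depth_thr or dur < min_dur:
            continue
        placements.append(FootPlacement(float(imu.t[b0 + k]), 0, 0))
    if not placements:
        raise NoStridesError("no stride cycles passed the depth/duration filters")
    return placements


def segment_staircases(
    placements: list[FootPlacement],
    stride_period_s: float,
    gap_factor: float = 1.75,
) -> list[list[FootPlacement]]:
    """Split placements into staircase traversals at long gaps.

    Consecutive placements further apart than ``gap_factor`` stride periods
    are taken to belong to different staircases (the walker crosses a
    landing in between).  Steps are numbered sequentially within each bout:
    the first placement on a staircase is step 1.
    """
    if not placements:
        return []
    times = [p.t for p in placements]
    bouts: list[list[float]] = [[times[0]]]
    for prev, cur in zip(times, times[1:]):
        if cur - prev > gap_factor * stride_period_s:
            bouts.append([])
        bouts[-1].append(cur)
    return [
        [FootPlacement(t, si + 1, k + 1) for k, t in enumerate(bout)]
        for si, bout in enumerate(bouts)
    ]


def stair_interval(placements: list[FootPlacement]) -> StairInterval | None:
    """First-to-last placement span of one staircase; None if under 2 placements."""
    if len(placements) < 2:
        return None
    return StairInterval(placements[0].t, placements[-1].t)


def time_on_staircase(per_staircase: list[list[FootPlacement]]) -> float:
    """Total time on the stairs for one walk: sum over staircases of
    (last placement - first placement).  NaN when any staircase is missing
    or has fewer than two placements."""
    total = 0.0
    for placements in per_staircase:
        iv = stair_interval(placements)
        if iv is None:
            return float("nan")
        total += iv.last_step_t - iv.first_step_t
    if not per_staircase:
        return float("nan")
    return total


def analysis_window(interval: StairInterval) -> tuple[float, float]:
    """Closed time window [first placement - 2 s, last placement] within which
    gaze counts toward this staircase's analyses."""
    return (interval.window_start_t, interval.last_step_t)
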