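"""Velocity-based saccade detection with a session-adaptive threshold.

A stretch of the recording belongs to a saccade when the dot product of the
gaze velocity on consecutive samples exceeds 10 times the median absolute
value of that dot product over the whole session (one walk).  The dot
product rewards motion that is both fast and consistent in direction, which
is what distinguishes saccades from fixational jitter.  Candidates below a
3 deg amplitude floor are discarded, and of two saccades closer than 100 ms
the slower one (lower peak speed) is removed.

Directions are head-fixed: 0 deg is upward in the scene camera, 90 deg is
rightward.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .traces import GazeTrace

logger = logging.getLogger(__name__)


class BlinkIntervalError(ValueError):
    """Raised for inverted or overlapping blink intervals."""


@dataclass(frozen=True)
class DetectorConfig:
    """Detector constants; defaults are the published values."""

    threshold_multiplier: float = 10.0
    min_amplitude_deg: float = 3.0
    min_interval_s: float = 0.100
    #: a candidate needs this many consecutive supra-threshold dot products
    #: (i.e. min_consistent_samples + 2 samples of consistent fast motion)
    min_consistent_samples: int = 2

    def __post_init__(self) -> None:
        if self.threshold_multiplier <= 0 or self.min_interval_s <= 0:
            raise ValueError("detector constants must be strictly positive")
        if self.min_amplitude_deg < 0 or self.min_consistent_samples < 1:
            raise ValueError("invalid detector configuration")


@dataclass(frozen=True)
class SaccadeEvent:
    onset_s: float
    offset_s: float
    amplitude_deg: float
    direction_deg: float
    peak_speed: float

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("saccade offset must follow onset")


@dataclass
class VelocitySeries:
    """Two-point finite-difference gaze velocities on contiguous valid runs.

    ``dot_next[i]`` is v_i . v_{i+1}; it is defined (``dot_defined[i]``) only
    when both velocities belong to the same contiguous run of valid samples.
    ``gaze_index[i]`` is the index of the left-hand gaze sample of v_i.
    """

    t_mid: np.ndarray
    v_az: np.ndarray
    v_el: np.ndarray
    gaze_index: np.ndarray
    run_id: np.ndarray
    dot_next: np.ndarray = field(init=False)
    dot_defined: np.ndarray = field(init=False)
    trace: GazeTrace | None = None

    def __post_init__(self) -> None:
        n = len(self.v_az)
        dot = np.zeros(n)
        defined = np.zeros(n, dtype=bool)
        if n > 1:
            same = self.run_id[:-1] == self.run_id[1:]
            dot[:-1][same] = (
                self.v_az[:-1] * self.v_az[1:] + self.v_el[:-1] * self.v_el[1:]
            )[same]
            defined[:-1] = same
        self.dot_next = dot
        self.dot_defined = defined

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.v_az, self.v_el)

    def __len__(self) -> int:
        return len(self.v_az)


def remove_blinks(gaze: GazeTrace, blinks: list[tuple[float, float]]) -> GazeTrace:
    """Mark samples inside blink intervals (closed endpoints) as invalid."""
    if not blinks:
        return GazeTrace(gaze.t, gaze.az, gaze.el, gaze.valid.copy())
    ivals = sorted((float(a), float(b)) for a, b in blinks)
    for a, b in ivals:
        if b <= a:
            raise BlinkIntervalError(f"inverted blink interval ({a}, {b})")
    for (_, b0), (a1, _) in zip(ivals, ivals[1:]):
        if a1 < b0:
            raise BlinkIntervalError("overlapping blink intervals")
    valid = gaze.valid.copy()
    for a, b in ivals:
        valid &= ~((gaze.t >= a) & (gaze.t <= b))
    return GazeTrace(gaze.t, gaze.az, gaze.el, valid)


def compute_velocity(gaze: GazeTrace) -> VelocitySeries:
    """Finite-difference velocity per consecutive valid sample pair.

    Returns an empty series when no contiguous run holds two valid samples.
    """
    idx = np.flatnonzero(gaze.valid)
    if len(idx) < 2:
        return VelocitySeries(
            np.empty(0), np.empty(0), np.empty(0),
            np.empty(0, dtype=int), np.empty(0, dtype=int), trace=gaze,
        )
    # runs of consecutive valid indices
    breaks = np.flatnonzero(np.diff(idx) != 1)
    run_of_valid = np.zeros(len(idx), dtype=int)
    run_of_valid[breaks + 1] = 1
    run_of_valid = np.cumsum(run_of_valid)
    # velocity exists between consecutive valid samples within one run
    pair_ok = np.diff(idx) == 1
    left = idx[:-1][pair_ok]
    dt = gaze.t[left + 1] - gaze.t[left]
    v_az = (gaze.az[left + 1] - gaze.az[left]) / dt
    v_el = (gaze.el[left + 1] - gaze.el[left]) / dt
    t_mid = 0.5 * (gaze.t[left + 1] + gaze.t[left])
    run_id = run_of_valid[:-1][pair_ok]
    return VelocitySeries(t_mid, v_az, v_el, left, run_id, trace=gaze)


def session_median(vel: VelocitySeries) -> float:
    """Median absolute velocity dot product over the session."""
    if not np.any(vel.dot_defined):
        return 0.0
    return float(np.median(np.abs(vel.dot_next[vel.dot_defined])))


def saccade_direction(d_az: float, d_el: float) -> float:
    """Head-fixed direction of a displacement: up = 0 deg, right = 90 deg."""
    if d_az == 0.0 and d_el == 0.0:
        raise ValueError("direction undefined for zero displacement")
    return math.degrees(math.atan2(d_az, d_el)) % 360.0


def _candidate_spans(vel: VelocitySeries, threshold: float, m_session: float, min_consistent: int):
    """Maximal runs of supra-threshold dot products, refined to speed minima.

    Yields velocity-index spans [v0, v1] (inclusive).  Each raw run of dot
    indices i..j (all > threshold, same contiguous segment) spans velocities
    i..j+1; the span is then extended outward while the adjacent speed keeps
    strictly decreasing and stays clearly above the fixational baseline
    (squared speed above twice the session median dot product), so the slow
    tails of the saccade are included in the amplitude measurement without
    swallowing drift samples.  Overlapping refined spans are merged.
    """
    supra = vel.dot_defined & (vel.dot_next > threshold)
    if not np.any(supra):
        return []
    speed = vel.speed
    floor2 = 2.0 * m_session
    spans = []
    n = len(vel)
    i = 0
    while i < n:
        if not supra[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and supra[j + 1]:
            j += 1
        if j - i + 1 >= min_consistent:
            v0, v1 = i, j + 1
            rid = vel.run_id[v0]
            while (
                v0 - 1 >= 0
                and vel.run_id[v0 - 1] == rid
                and speed[v0 - 1] < speed[v0]
                and speed[v0 - 1] ** 2 > floor2
            ):
                v0 -= 1
            while (
                v1 + 1 < n
                and vel.run_id[v1 + 1] == rid
                and speed[v1 + 1] < speed[v1]
                and speed[v1 + 1] ** 2 > floor2
            ):
                v1 += 1
            spans.append([v0, v1])
        i = j + 1
    merged: list[list[int]] = []
    for s in spans:
        if merged and s[0] <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], s[1])
        else:
            merged.append(s)
    return merged


def _prune_refractory(events: list[SaccadeEvent], min_interval_s: float) -> list[SaccadeEvent]:
    """Repeatedly drop the slower of any two saccades closer than the minimum
    interval (later one on equal peak speed) until all gaps are legal."""
    events = sorted(events, key=lambda e: e.onset_s)
    while True:
        for k in range(len(events) - 1):
            if events[k + 1].onset_s - events[k].offset_s < min_interval_s:
                a, b = events[k], events[k + 1]
                drop = k + 1 if b.peak_speed <= a.peak_speed else k
                logger.debug(
                    "refractory rule: removing saccade at %.3f s (peak %.1f deg/s)",
                    events[drop].onset_s, events[drop].peak_speed,
                )
                del events[drop]
                break
        else:
            return events


def detect_saccades(vel: VelocitySeries, cfg: DetectorConfig = DetectorConfig()) -> list[SaccadeEvent]:
    """Detect saccades in one session's velocity series.

    The threshold is ``cfg.threshold_multiplier`` times the session median of
    the absolute consecutive-velocity dot product.  A zero median (perfectly
    still gaze) yields no saccades and a warning.
    """
    if vel.trace is None:
        raise ValueError("velocity series lacks its source gaze trace")
    m = session_median(vel)
    if m == 0.0:
        logger.warning("session median dot product is zero; no saccades detected")
        return []
    threshold = cfg.threshold_multiplier * m
    gaze = vel.trace
    events = []
    for v0, v1 in _candidate_spans(vel, threshold, m, cfg.min_consistent_samples):
        g0 = int(vel.gaze_index[v0])
        g1 = int(vel.gaze_index[v1]) + 1
        d_az = gaze.az[g1] - gaze.az[g0]
        d_el = gaze.el[g1] - gaze.el[g0]
        amp = float(np.hypot(d_az, d_el))
        if amp < cfg.min_amplitude_deg:
            continue
        events.append(
            SaccadeEvent(
                onset_s=float(gaze.t[g0]),
                offset_s=float(gaze.t[g1]),
                amplitude_deg=amp,
                direction_deg=saccade_direction(float(d_az), float(d_el)),
                peak_speed=float(np.max(vel.speed[v0 : v1 + 1])),
            )
        )
    return _prune_refractory(events, cfg.min_interval_s)


def bin_directions(
    saccades: list[SaccadeEvent],
    bin_width_deg: float = 9.0,
    min_amplitudes: tuple[float, ...] | None = None,
) -> np.ndarray | dict[float, np.ndarray]:
    """Histogram saccade directions into half-open bins [k*w, (k+1)*w).

    With ``min_amplitudes`` given, returns one histogram per minimum-amplitude
    class (saccades at or above each floor), as in the shaded polar plots.
    """
    if 360.0 % bin_width_deg != 0.0:
        raise ValueError(f"bin width {bin_width_deg} does not divide 360")
    n_bins = int(round(360.0 / bin_width_deg))

    def _hist(events: list[SaccadeEvent]) -> np.ndarray:
        counts = np.zeros(n_bins, dtype=int)
        for e in events:
            counts[int(e.direction_deg // bin_width_deg) % n_bins] += 1
        return counts

    if min_amplitudes is None:
        return _hist(saccades)
    return {
        float(a): _hist([e for e in saccades if e.amplitude_deg >= a])
        for a in min_amplitudes
    }


def mean_saccade_amplitude(saccades_by_staircase: tuple[list[SaccadeEvent], list[SaccadeEvent]]) -> float:
    """Per-participant mean amplitude, averaged across the two staircases.

    Mean of the two per-staircase means when both staircases have saccades,
    the existing mean when only one does, NaN (missing) when neither does.
    """
    means = [
        float(np.mean([e.amplitude_deg for e in evs]))
        for evs in saccades_by_staircase
        if len(evs) > 0
    ]
    if not means:
        return float("nan")
    return float(np.mean(means))
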