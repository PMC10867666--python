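"""End-to-end analysis: events -> sequences -> per-participant summaries ->
group statistics.

``analyze_recording`` runs every stage on one walk; ``analyze_cohort``
collects the per-participant dependent variables and runs the mixed ANOVAs,
correlations and the detector-threshold diagnostic.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coding, gait, saccades, sequence, stats
from .config import RunConfig
from .saccades import SaccadeEvent
from .sequence import ParticipantSummary, TransitionHistogram
from .synth import Recording
from .traces import GazeTrace

logger = logging.getLogger(__name__)

DVS = ("fraction_fixated", "mean_amp_deg", "time_on_stairs_s")


@dataclass
class WalkResult:
    """Everything the pipeline derives from one walk."""

    summary: ParticipantSummary
    saccades_all: list[SaccadeEvent]
    saccades_by_staircase: list[list[SaccadeEvent]]
    sequences: list[coding.GazeSequence]
    placements: list[list[gait.FootPlacement]]
    windows: list[tuple[float, float]]
    m_session: float


def analyze_recording(rec: Recording, cfg: RunConfig = RunConfig()) -> WalkResult:
    """Run blink removal, saccade detection, gait segmentation, fixation
    coding and sequence statistics on one walk."""
    pid, direction = rec.meta.participant, rec.meta.direction

    # saccades over the whole session (one walk = one session)
    clean: GazeTrace = saccades.remove_blinks(rec.gaze, rec.blinks)
    vel = saccades.compute_velocity(clean)
    m_session = saccades.session_median(vel)
    events = saccades.detect_saccades(vel, cfg.detector)
    logger.info("%s/%s: %d saccades, m_session=%.2f", pid, direction, len(events), m_session)

    # gait: foot placements and per-staircase windows
    raw_placements = gait.detect_foot_placements(rec.imu, cfg.stride_period_s)
    bouts = gait.segment_staircases(raw_placements, cfg.stride_period_s)
    if len(bouts) != len(rec.staircases):
        logger.warning(
            "%s/%s: found %d staircase bouts, expected %d",
            pid, direction, len(bouts), len(rec.staircases),
        )
    intervals = [gait.stair_interval(b) for b in bouts]
    windows = [gait.analysis_window(iv) for iv in intervals if iv is not None]

    # fixation coding and per-staircase sequences
    fixations = coding.label_fixations(rec.frames, cfg.min_frames, cfg.strict_breaks)
    seqs = [
        coding.restrict_to_staircase(fixations, win, si + 1)
        for si, win in enumerate(windows)
    ]

    # sequence statistics
    hist = TransitionHistogram()
    for seq in seqs:
        hist = hist + sequence.transition_distribution(seq)
    frac = sequence.fraction_fixated(tuple(seqs), rec.staircases) if len(seqs) == 2 else float("nan")
    share = sequence.indirect_share(hist)

    # saccade metrics inside each staircase's window: from the first step
    # fixation (at or after 2 s before the first placement) to the last step
    sacc_by_stair: list[list[SaccadeEvent]] = []
    for seq, win in zip(seqs, windows):
        if seq.step_events:
            t0 = seq.step_events[0].start_s
            t1 = win[1]
            sacc_by_stair.append([e for e in events if t0 <= e.onset_s <= t1])
        else:
            sacc_by_stair.append([])
    mean_amp = saccades.mean_saccade_amplitude(tuple(sacc_by_stair[:2])) if len(sacc_by_stair) == 2 else float("nan")

    time_on = gait.time_on_staircase(bouts)

    summary = ParticipantSummary(
        participant=pid,
        group=rec.meta.group,
        direction=direction,
        fraction_fixated=frac,
        mean_amp_deg=mean_amp,
        time_on_stairs_s=time_on,
        indirect_share=share,
        transitions=hist,
        m_session=m_session,
    )
    return WalkResult(summary, events, sacc_by_stair, seqs, bouts, windows, m_session)


@dataclass
class CohortResult:
    summaries: list[ParticipantSummary]
    table: pd.DataFrame
    anovas: dict[str, stats.AnovaResult]
    correlations: dict[str, stats.CorrelationResult]
    pooled_histograms: dict[tuple[str, str], TransitionHistogram]
    pooled_indirect_share: dict[tuple[str, str], float]
    mean_indirect_share: dict[tuple[str, str], float]
    threshold_diag: stats.ThresholdDiagnostics | None
    config_hash: str = ""


def summaries_to_table(summaries: list[ParticipantSummary]) -> pd.DataFrame:
    """Long-format cohort table: one row per participant x direction x DV."""
    rows = []
    for s in summaries:
        for dv in DVS:
            rows.append(
                {
                    "participant": s.participant,
                    "group": s.group,
                    "direction": s.direction,
                    "dv": dv,
                    "value": getattr(s, dv),
                }
            )
    return pd.DataFrame(rows)


def analyze_cohort(
    results: list[WalkResult], cfg: RunConfig = RunConfig()
) -> CohortResult:
    summaries = [r.summary for r in results]
    table = summaries_to_table(summaries)

    anovas = {}
    for dv in DVS:
        try:
            anovas[dv] = stats.mixed_anova(table, dv)
        except ValueError as e:
            logger.warning("ANOVA on %s failed: %s", dv, e)

    correlations = {}
    for direction in stats.DIRECTIONS:
        sub = [s for s in summaries if s.direction == direction]
        x = [s.time_on_stairs_s for s in sub]
        y = [s.fraction_fixated for s in sub]
        try:
            correlations[direction] = stats.pearson_r(x, y)
        except ValueError as e:
            logger.warning("correlation (%s) failed: %s", direction, e)

    pooled: dict[tuple[str, str], TransitionHistogram] = {}
    shares_by_cell: dict[tuple[str, str], list[float]] = {}
    for s in summaries:
        key = (s.group, s.direction)
        pooled[key] = pooled.get(key, TransitionHistogram()) + s.transitions
        if not np.isnan(s.indirect_share):
            shares_by_cell.setdefault(key, []).append(s.indirect_share)
    pooled_share = {k: sequence.indirect_share(h) for k, h in pooled.items()}
    mean_share = {k: float(np.mean(v)) for k, v in shares_by_cell.items()}

    m_by_group: dict[str, list[float]] = {}
    for r in results:
        m_by_group.setdefault(r.summary.group, []).append(r.m_session)
    diag = None
    if len(m_by_group) >= 2 and all(len(v) >= 2 for v in m_by_group.values()):
        diag = stats.threshold_diagnostics(m_by_group)

    return CohortResult(
        summaries, table, anovas, correlations, pooled, pooled_share, mean_share,
        diag, cfg.hash(),
    )


def cohort_report(res: CohortResult) -> dict:
    """Machine-readable metrics bundle."""
    out: dict = {"config_hash": res.config_hash, "anova": {}, "correlation": {}}
    for dv, a in res.anovas.items():
        out["anova"][dv] = {
            name: dataclasses.asdict(eff) for name, eff in a.effects.items()
        }
        out["anova"][dv]["n_per_group"] = a.n_per_group
    for d, c in res.correlations.items():
        out["correlation"][d] = dataclasses.asdict(c)
    out["pooled_indirect_share"] = {
        f"{g}/{d}": v for (g, d), v in sorted(res.pooled_indirect_share.items())
    }
    cells: dict[str, dict] = {}
    for s in res.summaries:
        cell = cells.setdefault(f"{s.group}/{s.direction}", {"fraction_fixated": [], "mean_amp_deg": [], "time_on_stairs_s": []})
        for dv in DVS:
            cell[dv].append(getattr(s, dv))
    out["cell_means"] = {
        k: {dv: float(np.nanmean(v)) for dv, v in cell.items()} for k, cell in sorted(cells.items())
    }
    if res.threshold_diag is not None:
        out["threshold_diagnostics"] = dataclasses.asdict(res.threshold_diag)
    return out
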