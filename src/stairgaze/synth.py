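"""Synthetic gaze-and-gait walks with full ground truth.

The generator emulates a head-mounted eye-tracker recording of one walk
down or up two staircases (12 and 9 steps in walk order for descent,
reversed for ascent): a 200 Hz gaze trace in head-fixed degrees, a vertical
head-displacement trace with one minimum per step at the true foot
placement, a 30 Hz scene-frame label stream standing in for manual coding,
and blink intervals.  Every generated event is recorded as ground truth so
the downstream pipeline can be tested for exact recovery.

Model sketch
------------
* Each step of a staircase is fixated with probability ``p_fixate_step``;
  fixated steps are visited in travel order, so the *Direct* transition
  offsets beyond +1 arise from skipped steps.  Backward glances at already
  fixated steps are injected at the rate given by the negative entries of
  ``step_offset_weights``.
* Each transition between successive step fixations is independently
  indirect (detours via an elsewhere fixation) with probability
  ``p_indirect``; an indirect shift returns to the same step with
  probability ``p_indirect_return_same``, which produces the offset-0 peak
  of the Indirect distribution while keeping the expected indirect share
  exactly ``p_indirect``.
* While fixating a step the gaze tracks it as the walker advances, so even
  noise-free fixations carry a slow drift; saccades follow a minimum-jerk
  profile with duration 20 ms + 2 ms per degree.
* The head oscillates once per stride while on a staircase; the lowest head
  position within each stride is the foot-placement time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import StaircaseGeometry, staircases_for_direction
from .traces import ELSEWHERE, NONE_LABEL, FrameLabels, GazeTrace, ImuTrace, StepRef

GROUP_TAGS = {"stairs_relevant": "rel", "stairs_irrelevant": "irr"}
DIRECTIONS = ("descending", "ascending")

_MINJERK_PEAK = 1.875  # peak/mean velocity ratio of a minimum-jerk profile


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the synthetic walk generator.

    Probabilities are per-step / per-transition; angles in degrees, times in
    seconds, head displacement in metres.  ``direction_bias_deg`` is the
    circular bias of elsewhere-shift directions when *descending* (270 =
    leftward, toward the open side); ascent mirrors it.  The ``*_sd``
    heterogeneity fields act between participants (used by
    :func:`generate_cohort`), not within a walk.
    """

    group_label: str = "stairs_relevant"
    p_fixate_step: float = 0.8
    p_indirect: float = 0.09
    p_indirect_return_same: float = 0.35
    step_offset_weights: dict[int, float] = field(
        default_factory=lambda: {1: 0.90, -1: 0.07, -2: 0.03}
    )
    saccade_amp_mean_deg: float = 4.5
    saccade_amp_sd_deg: float = 1.0
    direction_bias_deg: float = 270.0
    direction_concentration: float = 1.5
    stride_period_s: float = 0.55
    ascending_stride_factor: float = 1.20
    stride_jitter_frac: float = 0.04
    walk_pace_sd: float = 0.05
    head_osc_amp: float = 0.05
    imu_noise_sd: float = 0.002
    gaze_noise_sd_deg: float = 0.15
    blink_rate_hz: float = 0.10
    blink_dur_s: float = 0.15
    gaze_rate_hz: float = 200.0
    frame_rate_hz: float = 30.0
    imu_rate_hz: float = 200.0
    timing_jitter_ms: float = 0.0
    # between-participant heterogeneity (cohort level)
    p_fixate_step_sd: float = 0.08
    p_indirect_sd: float = 0.04
    amp_between_sd: float = 0.5
    stride_between_sd: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_fixate_step", "p_indirect", "p_indirect_return_same"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "stride_period_s", "gaze_rate_hz", "frame_rate_hz", "imu_rate_hz",
            "blink_dur_s", "head_osc_amp", "saccade_amp_mean_deg",
            "ascending_stride_factor", "direction_concentration",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in (
            "saccade_amp_sd_deg", "gaze_noise_sd_deg", "imu_noise_sd",
            "blink_rate_hz", "stride_jitter_frac", "walk_pace_sd", "timing_jitter_ms",
            "p_fixate_step_sd", "p_indirect_sd", "amp_between_sd", "stride_between_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        w = self.step_offset_weights
        if not math.isclose(sum(w.values()), 1.0, abs_tol=1e-9):
            raise ValueError("step_offset_weights must sum to 1")
        if w.get(1, 0.0) <= 0.0:
            raise ValueError("step_offset_weights needs nonzero mass at offset +1")
        if any(int(k) != k or k == 0 for k in w):
            raise ValueError(
                "step_offset_weights keys are nonzero integers; same-step returns "
                "are governed by p_indirect_return_same"
            )
        if any(v < 0 for v in w.values()):
            raise ValueError("step_offset_weights must be non-negative")


def default_group_params(seed: int = 0) -> dict[str, GeneratorParams]:
    """Study-condition defaults for the two instruction groups."""
    return {
        "stairs_relevant": GeneratorParams(
            group_label="stairs_relevant",
            p_fixate_step=0.80,
            p_indirect=0.09,
            saccade_amp_mean_deg=4.5,
            direction_concentration=1.5,
            ascending_stride_factor=1.20,
            seed=seed,
        ),
        "stairs_irrelevant": GeneratorParams(
            group_label="stairs_irrelevant",
            p_fixate_step=0.60,
            p_indirect=0.23,
            saccade_amp_mean_deg=6.0,
            direction_concentration=3.0,
            ascending_stride_factor=1.32,
            seed=seed,
        ),
    }


def noise_free(params: GeneratorParams) -> GeneratorParams:
    """A copy with all measurement noise off (the drift of fixations that
    track steps while walking remains, so the detector threshold stays
    well defined)."""
    return replace(
        params,
        gaze_noise_sd_deg=0.0,
        imu_noise_sd=0.0,
        blink_rate_hz=0.0,
        timing_jitter_ms=0.0,
        stride_jitter_frac=0.0,
        walk_pace_sd=0.0,
    )


def implied_fraction_fixated(params: GeneratorParams) -> float:
    """Expected fraction of fixated steps under the generator model."""
    return params.p_fixate_step


def implied_indirect_share(params: GeneratorParams) -> float:
    """Expected share of indirect transitions under the generator model."""
    return params.p_indirect


@dataclass(frozen=True)
class TrueSaccade:
    onset_s: float
    offset_s: float
    amplitude_deg: float
    direction_deg: float
    peak_speed: float


@dataclass(frozen=True)
class TrueFixation:
    label: StepRef | str
    start_s: float
    end_s: float


@dataclass(frozen=True)
class AoiLayout:
    """Rectangular step regions in gaze coordinates; the column advances with
    walking progress (a step's centre elevation depends on how far ahead of
    the walker it lies)."""

    az_center: float
    el_base: float
    el_gain: float
    half_width: float
    half_height: float

    def center(self, step: int, progress: float) -> tuple[float, float]:
        return (self.az_center, self.el_base + self.el_gain * (step - progress))


@dataclass(frozen=True)
class ParticipantMeta:
    participant: str
    group: str
    direction: str


@dataclass
class Recording:
    gaze: GazeTrace
    imu: ImuTrace
    frames: FrameLabels
    blinks: list[tuple[float, float]]
    staircases: tuple[StaircaseGeometry, StaircaseGeometry]
    meta: ParticipantMeta


@dataclass
class GroundTruth:
    saccades: list[TrueSaccade]
    fixation_sequence: list[TrueFixation]
    foot_placements: list[np.ndarray]  # one array per staircase, walk order
    params: GeneratorParams
    layout: AoiLayout

    def sequence_for_staircase(self, stair: int) -> list[TrueFixation]:
        """The coded-sequence ground truth for one staircase: step fixations
        of that staircase with everything else pooled as elsewhere, trimmed
        to the first/last step fixation, adjacent elsewhere merged."""
        mapped: list[TrueFixation] = []
        for f in self.fixation_sequence:
            if isinstance(f.label, StepRef) and f.label.stair == stair:
                mapped.append(f)
            else:
                if mapped and mapped[-1].label == ELSEWHERE:
                    mapped[-1] = TrueFixation(ELSEWHERE, mapped[-1].start_s, f.end_s)
                else:
                    mapped.append(TrueFixation(ELSEWHERE, f.start_s, f.end_s))
        step_idx = [i for i, f in enumerate(mapped) if isinstance(f.label, StepRef)]
        if not step_idx:
            return []
        return mapped[step_idx[0] : step_idx[-1] + 1]

    def time_on_stairs(self) -> float:
        return float(sum(p[-1] - p[0] for p in self.foot_placements))


def progress_curve(placements: np.ndarray, stride: float):
    """Walker progress (in steps) as a function of time: step k is reached at
    its placement time, extended linearly beyond the staircase ends."""
    n = len(placements)
    steps = np.arange(1, n + 1, dtype=float)

    def c(t):
        t = np.asarray(t, dtype=float)
        out = np.interp(t, placements, steps)
        before = t < placements[0]
        after = t > placements[-1]
        out = np.where(before, 1.0 - (placements[0] - t) / stride, out)
        out = np.where(after, n + (t - placements[-1]) / stride, out)
        return out

    return c


def _minjerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


# ---------------------------------------------------------------------------
# visit-sequence construction


def _visit_labels(n_steps: int, params: GeneratorParams, rng: np.random.Generator):
    """Ordered list of visits for one staircase: StepRef-free step numbers and
    the string 'E' for elsewhere fixations."""
    fixated = [k for k in range(1, n_steps + 1) if rng.random() < params.p_fixate_step]
    if not fixated:
        return ["E", "E"]
    offsets = sorted(params.step_offset_weights)
    weights = np.array([params.step_offset_weights[o] for o in offsets])
    weights = weights / weights.sum()

    visits: list[int] = [fixated[0]]
    for k in fixated[1:]:
        prev = visits[-1]
        d = int(rng.choice(offsets, p=weights))
        if d <= -1:
            earlier = [s for s in fixated if s < prev]
            if earlier:
                target = min(earlier, key=lambda s: (abs(s - (prev + d)), s))
                visits.append(target)
        visits.append(k)

    out: list[int | str] = [visits[0]]
    for nxt in visits[1:]:
        cur = out[-1]
        if rng.random() < params.p_indirect:
            if rng.random() < params.p_indirect_return_same:
                out += ["E", cur]
                if rng.random() < params.p_indirect:
                    out.append("E")
            else:
                out.append("E")
        out.append(nxt)
    return out


def _block_starts(a: float, b: float, m: int, rng: np.random.Generator) -> np.ndarray:
    """m fixation-start times in [a, b], first exactly at a, jittered spacing."""
    if m == 1:
        return np.array([a])
    w = np.clip(1.0 + 0.15 * rng.standard_normal(m - 1), 0.5, 1.8)
    cum = np.concatenate([[0.0], np.cumsum(w)])
    return a + (b - a) * cum / cum[-1]


# ---------------------------------------------------------------------------


def generate_walk(
    params: GeneratorParams,
    staircases: tuple[StaircaseGeometry, StaircaseGeometry] | None = None,
    direction: str = "descending",
    participant: str = "p000",
    rng: np.random.Generator | None = None,
) -> tuple[Recording, GroundTruth]:
    """Generate one walk (both staircases) and its ground truth."""
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    if staircases is None:
        staircases = staircases_for_direction(direction)
    if rng is None:
        rng = np.random.default_rng(params.seed)

    stride = params.stride_period_s * (
        params.ascending_stride_factor if direction == "ascending" else 1.0
    )
    if params.walk_pace_sd > 0:
        stride *= float(np.clip(rng.normal(1.0, params.walk_pace_sd), 0.8, 1.25))

    # --- gait timeline: foot placements per staircase -----------------------
    placements: list[np.ndarray] = []
    t_cursor = rng.uniform(2.5, 3.5)  # pre-staircase roaming ends here
    for si, geo in enumerate(staircases):
        p1 = t_cursor + (1.2 if si == 0 else 0.0)
        jit = 1.0 + params.stride_jitter_frac * rng.standard_normal(geo.n_steps - 1)
        times = p1 + np.concatenate([[0.0], np.cumsum(stride * np.clip(jit, 0.5, 1.5))])
        placements.append(times)
        t_cursor = times[-1] + rng.uniform(2.5, 3.5)
    t_end = placements[-1][-1] + 2.0

    # --- fixation schedule ---------------------------------------------------
    # blocks of (visit labels, start-span); each fixation runs until the next
    # fixation's saccade onset
    blocks: list[tuple[list, float, float]] = []
    first_p = [p[0] for p in placements]
    last_p = [p[-1] for p in placements]
    pre_roam = ["E"] * rng.integers(2, 4)
    blocks.append((pre_roam, 0.2, first_p[0] - 1.9))
    for si, geo in enumerate(staircases):
        visits = _visit_labels(geo.n_steps, params, rng)
        labeled = [
            StepRef(si + 1, v) if isinstance(v, int) else ELSEWHERE for v in visits
        ]
        blocks.append((labeled, first_p[si] - 1.5, last_p[si] - 0.3))
        if si + 1 < len(staircases):
            mid = ["E"] * rng.integers(1, 3)
            blocks.append((mid, last_p[si] + 0.4, first_p[si + 1] - 1.9))
    blocks.append((["E"], last_p[-1] + 0.4, t_end - 1.0))

    labels: list[StepRef | str] = []
    starts: list[float] = []
    for visit_labels, a, b in blocks:
        vl = [ELSEWHERE if v == "E" else v for v in visit_labels]
        labels.extend(vl)
        starts.extend(_block_starts(a, max(b, a + 0.05), len(vl), rng))
    starts_arr = np.asarray(starts)
    if np.any(np.diff(starts_arr) < 0.12):
        warnings.warn("fixation dwell under 120 ms; sequence may be uncodable")

    # --- gaze targets --------------------------------------------------------
    el_gain = params.saccade_amp_mean_deg
    layout = AoiLayout(
        az_center=0.0,
        el_base=-20.0,
        el_gain=el_gain,
        half_width=2.0,
        half_height=max(1.6, 0.45 * el_gain),
    )
    curves = [progress_curve(p, stride) for p in placements]

    bias = params.direction_bias_deg
    if direction == "ascending":
        bias = (360.0 - bias) % 360.0
    kappa = params.direction_concentration

    # per-fixation position functions (noise-free target paths)
    scat_az = np.clip(0.6 * rng.standard_normal(len(labels)), -1.4, 1.4)
    scat_el = np.clip(0.35 * rng.standard_normal(len(labels)), -0.8, 0.8)
    pos_funcs = []
    prev_anchor = np.array([rng.uniform(-12, 12), rng.uniform(-6, 6)])
    for i, lab in enumerate(labels):
        if isinstance(lab, StepRef):
            c = curves[lab.stair - 1]
            step, saz, sel = lab.step, scat_az[i], scat_el[i]

            def pf(t, c=c, step=step, saz=saz, sel=sel):
                t = np.atleast_1d(np.asarray(t, dtype=float))
                az0, _ = layout.center(step, 0.0)
                el = layout.el_base + layout.el_gain * (step - c(t)) + sel
                return np.stack([np.full_like(el, az0 + saz), el])

            prev_anchor = pf(starts_arr[i])[:, 0]
        else:
            theta = rng.vonmises(math.radians(bias), kappa)
            amp = max(1.0, rng.normal(1.2 * params.saccade_amp_mean_deg, params.saccade_amp_sd_deg))
            point = prev_anchor + amp * np.array([math.sin(theta), math.cos(theta)])
            point[0] = float(np.clip(point[0], -34.0, 34.0))
            point[1] = float(np.clip(point[1], -34.0, 14.0))
            # keep elsewhere targets clear of the step column
            if abs(point[0] - layout.az_center) < layout.half_width + 0.8:
                side = 1.0 if (point[0] - layout.az_center) >= 0 else -1.0
                point[0] = layout.az_center + side * (layout.half_width + 0.8 + rng.uniform(0.5, 6.0))
            drift_dir = rng.uniform(0, 2 * math.pi)
            drift = 1.0 * np.array([math.sin(drift_dir), math.cos(drift_dir)])
            t0 = starts_arr[i]

            def pf(t, point=point.copy(), drift=drift, t0=t0):
                t = np.atleast_1d(np.asarray(t, dtype=float))
                return point[:, None] + drift[:, None] * (t - t0)[None, :]

            prev_anchor = point.copy()
        pos_funcs.append(pf)

    # --- saccades between fixations ------------------------------------------
    true_saccades: list[TrueSaccade] = []
    sacc_onsets = np.empty(len(labels))
    sacc_onsets[0] = starts_arr[0]
    for i in range(1, len(labels)):
        b = starts_arr[i]
        p1 = pos_funcs[i](b)[:, 0]
        dur = 0.030
        for _ in range(2):
            p0 = pos_funcs[i - 1](b - dur)[:, 0]
            amp = float(np.hypot(*(p1 - p0)))
            dur = 0.020 + 0.002 * amp
        onset = b - dur
        sacc_onsets[i] = onset
        d = p1 - p0
        direction_deg = math.degrees(math.atan2(d[0], d[1])) % 360.0
        true_saccades.append(
            TrueSaccade(onset, b, amp, direction_deg, _MINJERK_PEAK * amp / dur)
        )

    # fixation i spans [starts[i], sacc_onsets[i+1]]
    fix_ends = np.empty(len(labels))
    fix_ends[:-1] = sacc_onsets[1:]
    fix_ends[-1] = t_end
    truth_seq = [
        TrueFixation(lab, float(starts_arr[i]), float(fix_ends[i]))
        for i, lab in enumerate(labels)
    ]

    # --- sample the gaze trace ------------------------------------------------
    t_gaze = np.arange(0.0, t_end, 1.0 / params.gaze_rate_hz)
    if params.timing_jitter_ms > 0:
        t_gaze = t_gaze + rng.uniform(
            -params.timing_jitter_ms / 1000.0, params.timing_jitter_ms / 1000.0, len(t_gaze)
        )
        t_gaze = np.sort(t_gaze)
        keep = np.concatenate([[True], np.diff(t_gaze) > 1e-6])
        t_gaze = t_gaze[keep]
    az = np.empty(len(t_gaze))
    el = np.empty(len(t_gaze))
    # segment boundaries: fix_0 | sacc_1 fix_1 | sacc_2 fix_2 ...
    seg_bounds = [0.0]
    seg_kind: list[tuple[str, int]] = [("fix", 0)]
    for i in range(1, len(labels)):
        seg_bounds.append(sacc_onsets[i])
        seg_kind.append(("sacc", i - 1))
        seg_bounds.append(starts_arr[i])
        seg_kind.append(("fix", i))
    seg_idx = np.searchsorted(seg_bounds, t_gaze, side="right") - 1
    for s, (kind, i) in enumerate(seg_kind):
        mask = seg_idx == s
        if not np.any(mask):
            continue
        ts = t_gaze[mask]
        if kind == "fix":
            pos = pos_funcs[i](ts)
        else:
            sac = true_saccades[i]
            p0 = pos_funcs[i](np.array([sac.onset_s]))[:, 0]
            p1 = pos_funcs[i + 1](np.array([sac.offset_s]))[:, 0]
            tau = np.clip((ts - sac.onset_s) / (sac.offset_s - sac.onset_s), 0, 1)
            pos = p0[:, None] + (p1 - p0)[:, None] * _minjerk(tau)[None, :]
        az[mask] = pos[0]
        el[mask] = pos[1]
    if params.gaze_noise_sd_deg > 0:
        az += np.clip(
            rng.normal(0, params.gaze_noise_sd_deg, len(az)),
            -3 * params.gaze_noise_sd_deg, 3 * params.gaze_noise_sd_deg,
        )
        el += np.clip(
            rng.normal(0, params.gaze_noise_sd_deg, len(el)),
            -3 * params.gaze_noise_sd_deg, 3 * params.gaze_noise_sd_deg,
        )
    gaze = GazeTrace(t_gaze, az, el)

    # --- IMU -------------------------------------------------------------------
    t_imu = np.arange(0.0, t_end, 1.0 / params.imu_rate_hz)
    z = np.zeros(len(t_imu))
    for si, p in enumerate(placements):
        c = curves[si](t_imu)
        on = (t_imu >= p[0] - stride / 2) & (t_imu <= p[-1] + stride / 2)
        env = np.minimum(
            np.clip((t_imu - (p[0] - stride / 2)) / (stride / 2), 0, 1),
            np.clip(((p[-1] + stride / 2) - t_imu) / (stride / 2), 0, 1),
        )
        z[on] += (-params.head_osc_amp * np.cos(2 * math.pi * (c - 1.0)) * env)[on]
    if params.imu_noise_sd > 0:
        z += rng.normal(0, params.imu_noise_sd, len(z))
    imu = ImuTrace(t_imu, z)

    # --- frame labels -----------------------------------------------------------
    t_frames = np.arange(0.0, t_end, 1.0 / params.frame_rate_hz)
    fi = np.searchsorted(starts_arr, t_frames, side="right") - 1
    frame_labels = np.empty(len(t_frames), dtype=object)
    for j, tf in enumerate(t_frames):
        i = fi[j]
        if i < 0 or tf > fix_ends[i]:
            frame_labels[j] = NONE_LABEL
        else:
            frame_labels[j] = str(labels[i])
    frames = FrameLabels(t_frames, frame_labels)

    # --- blinks ------------------------------------------------------------------
    blinks: list[tuple[float, float]] = []
    if params.blink_rate_hz > 0:
        n_blinks = rng.poisson(params.blink_rate_hz * t_end)
        raw = np.sort(rng.uniform(0.0, t_end - params.blink_dur_s, n_blinks))
        for s in raw:
            e = s + params.blink_dur_s
            if blinks and s <= blinks[-1][1]:
                blinks[-1] = (blinks[-1][0], max(blinks[-1][1], e))
            else:
                blinks.append((float(s), float(e)))

    meta = ParticipantMeta(participant, params.group_label, direction)
    rec = Recording(gaze, imu, frames, blinks, staircases, meta)
    truth = GroundTruth(true_saccades, truth_seq, placements, params, layout)
    return rec, truth


def _jittered(params: GeneratorParams, rng: np.random.Generator) -> GeneratorParams:
    """Per-participant parameter draw around the group condition."""
    return replace(
        params,
        p_fixate_step=float(np.clip(
            rng.normal(params.p_fixate_step, params.p_fixate_step_sd), 0.0, 1.0)),
        p_indirect=float(np.clip(
            rng.normal(params.p_indirect, params.p_indirect_sd), 0.0, 1.0)),
        saccade_amp_mean_deg=float(np.clip(
            rng.normal(params.saccade_amp_mean_deg, params.amp_between_sd), 3.2, 12.0)),
        stride_period_s=float(params.stride_period_s * np.clip(
            rng.normal(1.0, params.stride_between_sd), 0.7, 1.4)),
    )




def generate_cohort(
    group_params: dict[str, GeneratorParams],
    n_per_group: int,
    seed: int,
    heterogeneous: bool = True,
) -> list[tuple[Recording, GroundTruth]]:
    """Generate ``n_per_group`` participants per group, each walking both
    directions.  Per-recording seeds derive from the master seed through
    ``numpy`` SeedSequence spawn keys, so the cohort is reproducible and
    stable under reordering."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    for g in group_params:
        if g not in GROUP_TAGS:
            raise ValueError(f"unknown group label {g!r}")
    out: list[tuple[Recording, GroundTruth]] = []
    for gi, (group, params) in enumerate(sorted(group_params.items())):
        for i in range(n_per_group):
            pid = f"{GROUP_TAGS[group]}{i + 1:02d}"
            prng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(gi, i, 999)))
            p_i = _jittered(params, prng) if heterogeneous else params
            for di, direction in enumerate(DIRECTIONS):
                rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(gi, i, di)))
                out.append(generate_walk(p_i, None, direction, pid, rng))
    return out
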