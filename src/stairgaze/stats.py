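"""Inferential layer: 2x2 mixed ANOVA with partial eta squared, Pearson
correlation, cohort exclusion bookkeeping and the detector-threshold group
diagnostic.

The design is Group (between subjects: stairs-relevant vs stairs-irrelevant)
by Direction (within subjects: descending vs ascending), analysed with the
classical split-plot sums-of-squares decomposition (via pingouin, the same
package of choice for this design).  Partial eta squared is
SS_effect / (SS_effect + SS_error_of_that_effect).  Only participants with
both directions present enter the ANOVA (complete cases), which is what
yields the printed between-effect denominator df of n_complete - 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

logger = logging.getLogger(__name__)

GROUPS = ("stairs_relevant", "stairs_irrelevant")
DIRECTIONS = ("descending", "ascending")
ALPHA = 0.05

EXCLUSION_REASONS = ("ran", "phone_use", "others_present_descending", "no_show")


class ZeroVarianceError(ValueError):
    """Raised when an error term is zero and F is undefined."""


@dataclass(frozen=True)
class EffectResult:
    F: float
    df_num: int
    df_den: int
    p: float
    eta_p2: float


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult]
    n_per_group: dict[str, int]
    n_dropped_incomplete: int
    dv: str

    @property
    def n_complete(self) -> int:
        return sum(self.n_per_group.values())


@dataclass(frozen=True)
class ExclusionRecord:
    participant: str
    reason: str
    scope: str  # both_directions | descending_only

    def __post_init__(self) -> None:
        if self.reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.reason!r}")
        if self.scope not in ("both_directions", "descending_only"):
            raise ValueError(f"unknown exclusion scope {self.scope!r}")


def apply_exclusions(
    roster: pd.DataFrame, records: list[ExclusionRecord]
) -> tuple[dict[tuple[str, str], int], dict[str, set[str]]]:
    """Apply exclusion records to a cohort roster.

    ``roster`` needs columns ``participant`` and ``group``.  Returns per
    (group, direction) included counts and the included participant ids per
    direction.
    """
    known = set(roster["participant"])
    seen = set()
    for rec in records:
        if rec.participant not in known:
            raise ValueError(f"exclusion references unknown participant {rec.participant!r}")
        if rec.participant in seen:
            raise ValueError(f"participant {rec.participant!r} has multiple exclusion records")
        seen.add(rec.participant)

    excluded = {d: set() for d in DIRECTIONS}
    for rec in records:
        if rec.scope == "both_directions":
            for d in DIRECTIONS:
                excluded[d].add(rec.participant)
        else:
            excluded["descending"].add(rec.participant)

    included = {d: known - excluded[d] for d in DIRECTIONS}
    group_of = dict(zip(roster["participant"], roster["group"]))
    counts = {
        (g, d): sum(1 for p in included[d] if group_of[p] == g)
        for g in sorted(set(roster["group"]))
        for d in DIRECTIONS
    }
    return counts, included


def _complete_cases(table: pd.DataFrame, dv: str) -> pd.DataFrame:
    sub = table.loc[table["dv"] == dv, ["participant", "group", "direction", "value"]]
    sub = sub.dropna(subset=["value"])
    if sub.duplicated(["participant", "direction"]).any():
        raise ValueError(f"multiple rows per participant x direction for dv {dv!r}")
    n_dir = sub.groupby("participant")["direction"].nunique()
    complete = n_dir[n_dir == len(DIRECTIONS)].index
    dropped = sub["participant"].nunique() - len(complete)
    if dropped:
        logger.info("mixed_anova(%s): dropped %d incomplete participants", dv, dropped)
    out = sub[sub["participant"].isin(complete)].copy()
    out.attrs["n_dropped"] = int(dropped)
    return out


def mixed_anova(table: pd.DataFrame, dv: str) -> AnovaResult:
    """Mixed-design ANOVA (Group between x Direction within) on one DV.

    ``table`` is long format with columns participant, group, direction, dv
    (the DV name) and value.  Complete cases only; requires two groups with
    at least two participants each.
    """
    data = _complete_cases(table, dv)
    groups = data.groupby("participant")["group"].first()
    group_sizes = groups.value_counts().to_dict()
    if len(group_sizes) != 2:
        raise ValueError(f"need exactly 2 groups, got {sorted(group_sizes)}")
    if min(group_sizes.values()) < 2:
        raise ValueError("need at least 2 complete participants per group")

    values = data["value"].to_numpy(float)
    if np.allclose(values, values[0]):
        # no variance anywhere: every effect explains nothing
        n = len(groups)
        zero = lambda dfd: EffectResult(0.0, 1, dfd, 1.0, 0.0)
        dfd = n - 2
        return AnovaResult(
            {"group": zero(dfd), "direction": zero(dfd), "interaction": zero(dfd)},
            {str(g): int(c) for g, c in group_sizes.items()},
            data.attrs.get("n_dropped", 0),
            dv,
        )

    # zero error variance with non-zero effects leaves F undefined
    subj_mean = data.groupby("participant")["value"].mean()
    grp_of = groups
    between_err = float(
        sum((subj_mean[p] - subj_mean[grp_of == grp_of[p]].mean()) ** 2 for p in subj_mean.index)
    )
    cell_pred = data.groupby(["group", "direction"])["value"].transform("mean")
    subj_pred = data["participant"].map(subj_mean)
    grp_pred = data["group"].map(data.groupby("group")["value"].mean())
    within_err = float(((data["value"] - cell_pred - subj_pred + grp_pred) ** 2).sum())
    if between_err <= 1e-12 * np.var(values) * len(values) or within_err <= 1e-12 * np.var(values) * len(values):
        raise ZeroVarianceError(f"zero error variance for dv {dv!r}; F undefined")

    res = pg.mixed_anova(
        data=data, dv="value", within="direction", between="group", subject="participant"
    )
    res = res.set_index("Source")
    effects = {}
    for name, row_name in (("group", "group"), ("direction", "direction"), ("interaction", "Interaction")):
        row = res.loc[row_name]
        effects[name] = EffectResult(
            F=float(row["F"]),
            df_num=int(row["DF1"]),
            df_den=int(row["DF2"]),
            p=float(row["p_unc"]),
            eta_p2=float(row["np2"]),
        )
    return AnovaResult(
        effects,
        {str(g): int(c) for g, c in group_sizes.items()},
        data.attrs.get("n_dropped", 0),
        dv,
    )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson_r(x, y) -> CorrelationResult:
    """Product-moment correlation; requires n >= 3 finite pairs and variance
    in both variables."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need at least 3 finite pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined: zero variance")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), int(len(x)))


@dataclass
class ThresholdDiagnostics:
    """Group comparison of per-session detector medians (a sanity check that
    the adaptive threshold does not differ systematically between groups)."""

    group_mean: dict[str, float]
    group_sd: dict[str, float]
    group_n: dict[str, int]
    t: float
    p: float


def threshold_diagnostics(m_by_group: dict[str, list[float]]) -> ThresholdDiagnostics:
    groups = {g: np.asarray(v, float) for g, v in m_by_group.items() if len(v) > 0}
    if len(groups) < 2:
        raise ValueError("need sessions from at least two groups")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("need at least 2 sessions per group")
    (ga, va), (gb, vb) = list(groups.items())[:2]
    t, p = sps.ttest_ind(va, vb, equal_var=False)
    return ThresholdDiagnostics(
        {g: float(np.mean(v)) for g, v in groups.items()},
        {g: float(np.std(v, ddof=1)) for g, v in groups.items()},
        {g: int(len(v)) for g, v in groups.items()},
        float(t),
        float(p),
    )
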