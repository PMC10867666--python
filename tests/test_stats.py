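import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import stairgaze as sg
from stairgaze.stats import (
    ExclusionRecord,
    ZeroVarianceError,
    apply_exclusions,
    mixed_anova,
    pearson_r,
    threshold_diagnostics,
)

from .reference import naive_mixed_anova


def study_roster():
    """18 stairs-relevant + 16 stairs-irrelevant participants."""
    rows = [(f"rel{i:02d}", "stairs_relevant") for i in range(18)]
    rows += [(f"irr{i:02d}", "stairs_irrelevant") for i in range(16)]
    return pd.DataFrame(rows, columns=["participant", "group"])


def study_exclusions():
    """The three exclusions: one runner, one phone user (both directions),
    one walk with other people on the stairs (descending only)."""
    return [
        ExclusionRecord("rel00", "ran", "both_directions"),
        ExclusionRecord("irr00", "phone_use", "both_directions"),
        ExclusionRecord("irr01", "others_present_descending", "descending_only"),
    ]


def random_table(rng, n_a=6, n_b=6, group_effect=0.0, dir_effect=0.0):
    rows = []
    for g, n in (("stairs_relevant", n_a), ("stairs_irrelevant", n_b)):
        for i in range(n):
            pid = f"{g[7]}{i}"
            base = rng.normal(0, 1) + (group_effect if g == "stairs_relevant" else 0)
            for d in ("descending", "ascending"):
                rows.append(
                    {
                        "participant": pid, "group": g, "direction": d,
                        "dv": "fraction_fixated",
                        "value": base + rng.normal(0, 1) + (dir_effect if d == "ascending" else 0),
                    }
                )
    return pd.DataFrame(rows)


class TestApplyExclusions:
    def test_study_counts(self):
        counts, _ = apply_exclusions(study_roster(), study_exclusions())
        assert counts[("stairs_relevant", "descending")] == 17
        assert counts[("stairs_irrelevant", "descending")] == 14
        assert counts[("stairs_relevant", "ascending")] == 17
        assert counts[("stairs_irrelevant", "ascending")] == 15

    def test_no_records_is_identity(self):
        counts, _ = apply_exclusions(study_roster(), [])
        assert counts[("stairs_relevant", "descending")] == 18
        assert counts[("stairs_irrelevant", "ascending")] == 16

    def test_unknown_participant_rejected(self):
        with pytest.raises(ValueError):
            apply_exclusions(study_roster(), [ExclusionRecord("zzz", "ran", "both_directions")])

    def test_duplicate_record_rejected(self):
        recs = [
            ExclusionRecord("rel00", "ran", "both_directions"),
            ExclusionRecord("rel00", "phone_use", "both_directions"),
        ]
        with pytest.raises(ValueError):
            apply_exclusions(study_roster(), recs)

    def test_bad_reason_rejected(self):
        with pytest.raises(ValueError):
            ExclusionRecord("rel00", "sneezed", "both_directions")


class TestMixedAnova:
    def test_all_identical_values_give_zero_f(self):
        rng = np.random.default_rng(1)
        t = random_table(rng)
        t["value"] = 3.14
        res = mixed_anova(t, "fraction_fixated")
        for eff in res.effects.values():
            assert eff.F == 0.0 and eff.eta_p2 == 0.0

    def test_complete_case_dfs_match_study(self):
        """17 + 14 complete participants give df_den = 29 for every effect."""
        rng = np.random.default_rng(2)
        t = random_table(rng, n_a=17, n_b=15)
        # one stairs-irrelevant participant misses the descending walk
        drop = (t["participant"] == "i14") & (t["direction"] == "descending")
        res = mixed_anova(t[~drop], "fraction_fixated")
        assert res.n_per_group == {"stairs_relevant": 17, "stairs_irrelevant": 14}
        assert res.n_dropped_incomplete == 1
        for eff in res.effects.values():
            assert eff.df_num == 1 and eff.df_den == 29

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(13)
        t = random_table(rng, 6, 6, group_effect=0.5)
        res = mixed_anova(t, "fraction_fixated")
        rows = [
            (r.participant, r.group, r.direction, r.value) for r in t.itertuples()
        ]
        ref = naive_mixed_anova(rows)
        for name in ("group", "direction", "interaction"):
            assert res.effects[name].F == pytest.approx(ref[name]["F"], abs=1e-8)
            assert res.effects[name].p == pytest.approx(ref[name]["p"], abs=1e-8)
            assert res.effects[name].eta_p2 == pytest.approx(ref[name]["eta_p2"], abs=1e-8)

    def test_between_f_equals_squared_two_sample_t_on_subject_means(self):
        rng = np.random.default_rng(7)
        t = random_table(rng, 8, 5, group_effect=0.8)
        res = mixed_anova(t, "fraction_fixated")
        means = t.groupby("participant").agg({"value": "mean", "group": "first"})
        a = means.loc[means.group == "stairs_relevant", "value"]
        b = means.loc[means.group == "stairs_irrelevant", "value"]
        tt = sps.ttest_ind(a, b, equal_var=True)
        assert res.effects["group"].F == pytest.approx(tt.statistic**2, rel=1e-9)

    def test_within_f_equals_squared_paired_t_without_group_structure(self):
        """When the two groups' direction differences share the same mean by
        construction, the within-subject F equals the squared paired t up to
        the error-df ratio (N-2)/(N-1): the split-plot error loses one df to
        the group term that the one-sample paired test keeps."""
        rng = np.random.default_rng(19)
        base = rng.normal(0, 1, 6)
        diffs = rng.normal(0.7, 1, 6)
        rows = []
        for g in ("stairs_relevant", "stairs_irrelevant"):
            for i in range(6):
                pid = f"{g[7]}{i}"
                off = rng.normal(0, 1)
                rows.append({"participant": pid, "group": g, "direction": "descending",
                             "dv": "x", "value": base[i] + off})
                rows.append({"participant": pid, "group": g, "direction": "ascending",
                             "dv": "x", "value": base[i] + off + diffs[i]})
        t = pd.DataFrame(rows)
        res = mixed_anova(t, "x")
        d = t.pivot_table(index="participant", columns="direction", values="value")
        tt = sps.ttest_rel(d["ascending"], d["descending"])
        n = len(d)
        assert res.effects["direction"].F == pytest.approx(
            tt.statistic**2 * (n - 2) / (n - 1), rel=1e-9
        )

    def test_zero_error_variance_flagged(self):
        rows = []
        for g, gv in (("stairs_relevant", 0.0), ("stairs_irrelevant", 1.0)):
            for i in range(3):
                for d, dv_off in (("descending", 0.0), ("ascending", 0.5)):
                    rows.append({"participant": f"{g}{i}", "group": g, "direction": d,
                                 "dv": "x", "value": gv + dv_off})
        with pytest.raises(ZeroVarianceError):
            mixed_anova(pd.DataFrame(rows), "x")

    def test_single_group_rejected(self):
        rng = np.random.default_rng(3)
        t = random_table(rng)
        with pytest.raises(ValueError):
            mixed_anova(t[t.group == "stairs_relevant"], "fraction_fixated")


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1).r == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pearson_r([1, 2, 3], [3, 2, 1]).r == pytest.approx(-1.0)

    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(21)
        r = pearson_r(rng.normal(size=500), rng.normal(size=500)).r
        assert abs(r) < 0.15

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [1, 2])


class TestThresholdDiagnostics:
    def test_identical_groups_zero_difference(self):
        d = threshold_diagnostics({"a": [5.0, 5.0, 5.0], "b": [5.0, 5.0, 5.0]})
        assert d.group_mean["a"] == d.group_mean["b"]

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            threshold_diagnostics({"a": [1.0, 2.0]})

    def test_equal_noise_groups_close(self, small_cohort):
        """With identical gaze noise in both groups, the session medians do
        not differ systematically (within 2 standard errors)."""
        m = {}
        for rec, _ in small_cohort:
            res = sg.analyze_recording(rec)
            m.setdefault(rec.meta.group, []).append(res.m_session)
        d = threshold_diagnostics(m)
        (ga, gb) = sorted(m)
        sem = np.hypot(
            d.group_sd[ga] / np.sqrt(d.group_n[ga]),
            d.group_sd[gb] / np.sqrt(d.group_n[gb]),
        )
        assert abs(d.group_mean[ga] - d.group_mean[gb]) < 2 * sem
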