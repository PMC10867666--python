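"""Naive, loop-based reference implementations used as independent oracles.

Everything here recomputes results sample-by-sample with plain Python so
that the vectorised package code can be checked against an implementation
whose only virtue is being obviously faithful to the rules.
"""

from __future__ import annotations

import math
import statistics


# --------------------------------------------------------------------------
# saccade detector


def naive_detect(
    t,
    az,
    el,
    valid,
    multiplier=10.0,
    min_amplitude=3.0,
    min_interval=0.100,
    min_consistent=2,
):
    """Reference saccade detector.

    Returns a list of dicts with onset, offset, amplitude, direction and
    peak speed, following the same published rules as the package detector:
    dot-product threshold at ``multiplier`` times the session median,
    candidate runs of ``min_consistent`` consecutive supra-threshold dot
    products, boundary extension to the local speed minimum (while the
    outside squared speed stays above twice the session median), a minimum
    amplitude, and the slower-removed refractory rule.
    """
    n = len(t)
    # contiguous runs of valid samples
    runs = []
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and valid[j + 1]:
            j += 1
        if j > i:
            runs.append((i, j))
        i = j + 1

    # velocities per run: list of (gaze left index, vx, vy)
    vels = []
    run_id = []
    for rid, (a, b) in enumerate(runs):
        for k in range(a, b):
            dt = t[k + 1] - t[k]
            vels.append((k, (az[k + 1] - az[k]) / dt, (el[k + 1] - el[k]) / dt))
            run_id.append(rid)

    dots = []
    for m in range(len(vels) - 1):
        if run_id[m] == run_id[m + 1]:
            dots.append(vels[m][1] * vels[m + 1][1] + vels[m][2] * vels[m + 1][2])
    if not dots:
        return []
    med = statistics.median(abs(d) for d in dots)
    if med == 0.0:
        return []
    thr = multiplier * med
    floor2 = 2.0 * med

    def speed(m):
        return math.hypot(vels[m][1], vels[m][2])

    # supra-threshold dot runs -> velocity spans, refined
    spans = []
    m = 0
    n_v = len(vels)
    while m < n_v - 1:
        if run_id[m] != run_id[m + 1]:
            m += 1
            continue
        d = vels[m][1] * vels[m + 1][1] + vels[m][2] * vels[m + 1][2]
        if d <= thr:
            m += 1
            continue
        m0 = m
        while (
            m + 1 < n_v - 1
            and run_id[m + 1] == run_id[m + 2]
            and run_id[m] == run_id[m + 1]
            and vels[m + 1][1] * vels[m + 2][1] + vels[m + 1][2] * vels[m + 2][2] > thr
        ):
            m += 1
        run_len = m - m0 + 1
        if run_len >= min_consistent:
            v0, v1 = m0, m + 1
            rid = run_id[v0]
            while v0 - 1 >= 0 and run_id[v0 - 1] == rid and speed(v0 - 1) < speed(v0) and speed(v0 - 1) ** 2 > floor2:
                v0 -= 1
            while v1 + 1 < n_v and run_id[v1 + 1] == rid and speed(v1 + 1) < speed(v1) and speed(v1 + 1) ** 2 > floor2:
                v1 += 1
            spans.append([v0, v1])
        m += 1

    merged = []
    for s in spans:
        if merged and s[0] <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], s[1])
        else:
            merged.append(s)

    events = []
    for v0, v1 in merged:
        g0 = vels[v0][0]
        g1 = vels[v1][0] + 1
        d_az = az[g1] - az[g0]
        d_el = el[g1] - el[g0]
        amp = math.hypot(d_az, d_el)
        if amp < min_amplitude:
            continue
        events.append(
            {
                "onset": t[g0],
                "offset": t[g1],
                "amplitude": amp,
                "direction": math.degrees(math.atan2(d_az, d_el)) % 360.0,
                "peak_speed": max(speed(m) for m in range(v0, v1 + 1)),
            }
        )

    # refractory pruning: slower of any pair closer than min_interval
    changed = True
    while changed:
        changed = False
        for k in range(len(events) - 1):
            if events[k + 1]["onset"] - events[k]["offset"] < min_interval:
                if events[k + 1]["peak_speed"] <= events[k]["peak_speed"]:
                    del events[k + 1]
                else:
                    del events[k]
                changed = True
                break
    return events


# --------------------------------------------------------------------------
# split-plot ANOVA sums of squares


def naive_mixed_anova(rows):
    """Classical cell-means/subject-means decomposition of a 2 (between) x
    2 (within) design.  ``rows`` is a list of (subject, group, level, value)
    with every subject complete.  Returns per-effect (F, df1, df2, p,
    eta_p2) computed with plain loops."""
    from scipy.stats import f as fdist

    subjects = sorted({r[0] for r in rows})
    groups = sorted({r[1] for r in rows})
    levels = sorted({r[2] for r in rows})
    a, b = len(groups), len(levels)
    assert a == 2 and b == 2
    val = {(r[0], r[2]): r[3] for r in rows}
    grp = {r[0]: r[1] for r in rows}
    n_g = {g: sum(1 for s in subjects if grp[s] == g) for g in groups}
    N = len(subjects)

    grand = sum(val[(s, l)] for s in subjects for l in levels) / (N * b)
    subj_mean = {s: sum(val[(s, l)] for l in levels) / b for s in subjects}
    group_mean = {
        g: sum(subj_mean[s] for s in subjects if grp[s] == g) / n_g[g] for g in groups
    }
    level_mean = {l: sum(val[(s, l)] for s in subjects) / N for l in levels}
    cell_mean = {
        (g, l): sum(val[(s, l)] for s in subjects if grp[s] == g) / n_g[g]
        for g in groups
        for l in levels
    }

    ss_group = sum(b * n_g[g] * (group_mean[g] - grand) ** 2 for g in groups)
    ss_subj_within = sum(b * (subj_mean[s] - group_mean[grp[s]]) ** 2 for s in subjects)
    ss_level = sum(N * (level_mean[l] - grand) ** 2 for l in levels)
    ss_cells = sum(
        n_g[g] * (cell_mean[(g, l)] - grand) ** 2 for g in groups for l in levels
    )
    ss_inter = ss_cells - ss_group - ss_level
    ss_total = sum((val[(s, l)] - grand) ** 2 for s in subjects for l in levels)
    ss_err_within = ss_total - ss_cells - ss_subj_within

    df_g, df_eg = a - 1, N - a
    df_l, df_el = b - 1, (N - a) * (b - 1)
    out = {}
    for name, ss_eff, df1, ss_err, df2 in (
        ("group", ss_group, df_g, ss_subj_within, df_eg),
        ("direction", ss_level, df_l, ss_err_within, df_el),
        ("interaction", ss_inter, (a - 1) * (b - 1), ss_err_within, df_el),
    ):
        F = (ss_eff / df1) / (ss_err / df2)
        out[name] = {
            "F": F,
            "df1": df1,
            "df2": df2,
            "p": float(fdist.sf(F, df1, df2)),
            "eta_p2": ss_eff / (ss_eff + ss_err),
        }
    return out


# --------------------------------------------------------------------------
# small helpers


def naive_bin_directions(directions, width):
    counts = [0] * int(360 // width)
    for d in directions:
        counts[int(d // width) % len(counts)] += 1
    return counts


def naive_interval_members(times, start, end):
    return [i for i, tt in enumerate(times) if start <= tt <= end]


def naive_cycle_minima(t, z, boundaries):
    """Per-cycle argmin oracle: boundaries are index pairs."""
    out = []
    for a, b in boundaries:
        best = a
        for k in range(a, b):
            if z[k] < z[best]:
                best = k
        out.append(t[best])
    return out
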