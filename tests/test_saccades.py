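import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stairgaze as sg
from stairgaze.saccades import (
    BlinkIntervalError,
    DetectorConfig,
    SaccadeEvent,
    _prune_refractory,
    bin_directions,
    compute_velocity,
    detect_saccades,
    mean_saccade_amplitude,
    remove_blinks,
    saccade_direction,
    session_median,
)
from stairgaze.traces import GazeTrace

from .conftest import random_gaze_trace
from .reference import naive_bin_directions, naive_detect, naive_interval_members


def _trace(t, az, el):
    return GazeTrace(np.asarray(t, float), np.asarray(az, float), np.asarray(el, float))


def _drifting_trace_with_saccade(amp=4.0, theta_deg=90.0, dur=0.050, dt=0.005):
    """1 s drifting fixation, one minimum-jerk saccade, 1 s drifting fixation."""
    t = np.arange(0, 2.0 + dur, dt)
    az = np.empty_like(t)
    el = np.empty_like(t)
    drift = 1.5  # deg/s, keeps the session median positive
    pre = t <= 1.0
    az[pre] = drift * t[pre]
    el[pre] = 0.3 * drift * t[pre]
    start = np.array([drift, 0.3 * drift])
    d = amp * np.array(
        [math.sin(math.radians(theta_deg)), math.cos(math.radians(theta_deg))]
    )
    sacc = (t > 1.0) & (t <= 1.0 + dur)
    tau = (t[sacc] - 1.0) / dur
    prof = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    az[sacc] = start[0] + d[0] * prof
    el[sacc] = start[1] + d[1] * prof
    post = t > 1.0 + dur
    az[post] = start[0] + d[0] + drift * (t[post] - 1.0 - dur)
    el[post] = start[1] + d[1] + 0.3 * drift * (t[post] - 1.0 - dur)
    return _trace(t, az, el)


class TestRemoveBlinks:
    def test_empty_list_is_identity(self):
        g = _trace([0, 0.1, 0.2], [1, 2, 3], [0, 0, 0])
        out = remove_blinks(g, [])
        assert np.all(out.valid)

    def test_full_cover_blink_kills_all_saccades(self):
        g = _drifting_trace_with_saccade()
        out = remove_blinks(g, [(g.t[0], g.t[-1])])
        assert not np.any(out.valid)
        assert detect_saccades(compute_velocity(out)) == []

    def test_interval_membership_matches_brute_force(self):
        rng = np.random.default_rng(4)
        t = np.cumsum(rng.uniform(0.004, 0.006, 400))
        g = _trace(t, np.zeros(400), np.zeros(400))
        out = remove_blinks(g, [(1.0, 1.2)])
        expect_invalid = naive_interval_members(t, 1.0, 1.2)
        assert sorted(np.flatnonzero(~out.valid)) == expect_invalid

    def test_bad_intervals_rejected(self):
        g = _trace([0, 1, 2], [0, 0, 0], [0, 0, 0])
        with pytest.raises(BlinkIntervalError):
            remove_blinks(g, [(1.0, 0.5)])
        with pytest.raises(BlinkIntervalError):
            remove_blinks(g, [(0.0, 1.0), (0.5, 1.5)])


class TestComputeVelocity:
    def test_constant_gaze_all_zero(self):
        g = _trace(np.arange(10) * 0.005, np.ones(10), np.ones(10))
        v = compute_velocity(g)
        assert np.allclose(v.v_az, 0) and np.allclose(v.v_el, 0)
        assert np.allclose(v.dot_next[v.dot_defined], 0)

    def test_linear_motion(self):
        t = np.arange(100) * 0.005
        g = _trace(t, 40.0 * t, np.zeros_like(t))
        v = compute_velocity(g)
        assert np.allclose(v.v_az, 40.0)
        assert np.allclose(v.dot_next[v.dot_defined], 1600.0)

    def test_dot_products_match_loop_oracle(self):
        rng = np.random.default_rng(3)
        g = random_gaze_trace(rng, n=500)
        v = compute_velocity(g)
        # recompute v_i . v_{i+1} sample by sample
        for i in np.flatnonzero(v.dot_defined):
            expect = v.v_az[i] * v.v_az[i + 1] + v.v_el[i] * v.v_el[i + 1]
            assert v.dot_next[i] == pytest.approx(expect, rel=1e-12)

    def test_too_few_valid_samples_gives_empty(self):
        g = GazeTrace(np.array([0.0, 0.005]), np.zeros(2), np.zeros(2),
                      np.array([True, False]))
        assert len(compute_velocity(g)) == 0


class TestDetectSaccades:
    def test_still_gaze_with_noise_has_no_saccades(self):
        rng = np.random.default_rng(0)
        t = np.arange(1000) * 0.005
        g = _trace(t, rng.normal(0, 0.05, 1000), rng.normal(0, 0.05, 1000))
        assert detect_saccades(compute_velocity(g)) == []

    def test_perfectly_still_gaze_warns_and_returns_empty(self, caplog):
        g = _trace(np.arange(100) * 0.005, np.zeros(100), np.zeros(100))
        with caplog.at_level("WARNING"):
            out = detect_saccades(compute_velocity(g))
        assert out == []
        assert any("median" in r.message for r in caplog.records)

    def test_single_4deg_rightward_saccade_recovered(self):
        g = _drifting_trace_with_saccade(amp=4.0, theta_deg=90.0)
        events = detect_saccades(compute_velocity(g))
        assert len(events) == 1
        e = events[0]
        assert e.amplitude_deg == pytest.approx(4.0, abs=0.2)
        assert 45 < e.direction_deg < 135  # rightward

    def test_sub_threshold_amplitude_discarded(self):
        g29 = _drifting_trace_with_saccade(amp=2.9)
        g31 = _drifting_trace_with_saccade(amp=3.1)
        assert detect_saccades(compute_velocity(g29)) == []
        assert len(detect_saccades(compute_velocity(g31))) == 1

    def test_matches_naive_reference_on_random_traces(self):
        rng = np.random.default_rng(17)
        cfg = DetectorConfig()
        for _ in range(10):
            g = random_gaze_trace(rng)
            mine = detect_saccades(compute_velocity(g), cfg)
            ref = naive_detect(list(g.t), list(g.az), list(g.el), list(g.valid))
            assert len(mine) == len(ref)
            for e, r in zip(mine, ref):
                assert e.onset_s == pytest.approx(r["onset"], abs=1e-12)
                assert e.offset_s == pytest.approx(r["offset"], abs=1e-12)
                assert e.amplitude_deg == pytest.approx(r["amplitude"], rel=1e-9)

    def test_threshold_scale_invariance(self):
        """Scaling all gaze angles by c scales dot products and their median
        by c^2, leaving the candidate event set unchanged (amplitude floor
        scaled along to isolate the thresholding)."""
        rng = np.random.default_rng(23)
        g = random_gaze_trace(rng, n=800)
        c = 7.3
        g2 = GazeTrace(g.t, c * g.az, c * g.el, g.valid)
        cfg1 = DetectorConfig(min_amplitude_deg=1.0)
        cfg2 = DetectorConfig(min_amplitude_deg=c * 1.0)
        e1 = detect_saccades(compute_velocity(g), cfg1)
        e2 = detect_saccades(compute_velocity(g2), cfg2)
        assert [(e.onset_s, e.offset_s) for e in e1] == [(e.onset_s, e.offset_s) for e in e2]
        for a, b in zip(e1, e2):
            assert b.amplitude_deg == pytest.approx(c * a.amplitude_deg, rel=1e-9)


class TestRefractoryRule:
    def _ev(self, onset, peak, dur=0.03):
        return SaccadeEvent(onset, onset + dur, 5.0, 0.0, peak)

    def test_slower_of_close_pair_removed(self):
        fast, slow = self._ev(1.0, 300.0), self._ev(1.11, 150.0)  # 80 ms gap
        out = _prune_refractory([fast, slow], 0.100)
        assert out == [fast]

    def test_equal_peaks_drop_later(self):
        a, b = self._ev(1.0, 200.0), self._ev(1.11, 200.0)
        assert _prune_refractory([a, b], 0.100) == [a]

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.floats(0, 30), st.floats(10, 500)), max_size=15))
    def test_pruning_reaches_fixed_point(self, raw):
        events = [self._ev(round(o, 3), p) for o, p in sorted(raw)]
        events = [e for i, e in enumerate(events)
                  if i == 0 or e.onset_s > events[i - 1].onset_s]
        out = _prune_refractory(list(events), 0.100)
        # fixed point: all gaps legal and a second pass changes nothing
        for x, y in zip(out, out[1:]):
            assert y.onset_s - x.offset_s >= 0.100
        assert _prune_refractory(list(out), 0.100) == out


class TestDirectionsAndAmplitude:
    @pytest.mark.parametrize(
        "d_az,d_el,expected",
        [(0, 2, 0.0), (2, 0, 90.0), (-1, -1, 225.0), (0, -2, 180.0), (-2, 0, 270.0)],
    )
    def test_head_fixed_direction_convention(self, d_az, d_el, expected):
        assert saccade_direction(d_az, d_el) == pytest.approx(expected)

    def test_zero_displacement_is_undefined(self):
        with pytest.raises(ValueError):
            saccade_direction(0.0, 0.0)

    def test_forty_bins_of_nine_degrees(self):
        assert len(bin_directions([], 9.0)) == 40

    def test_half_open_bin_convention(self):
        evs = [SaccadeEvent(0, 0.1, 5, d, 100) for d in (0.0, 8.999, 9.0)]
        counts = bin_directions(evs, 9.0)
        assert counts[0] == 2 and counts[1] == 1

    def test_bin_counts_match_loop_oracle(self):
        rng = np.random.default_rng(11)
        dirs = rng.uniform(0, 360, 1000)
        evs = [SaccadeEvent(i * 0.2, i * 0.2 + 0.1, 5, d, 100) for i, d in enumerate(dirs)]
        counts = bin_directions(evs, 9.0)
        assert counts.sum() == 1000
        assert list(counts) == naive_bin_directions(dirs, 9.0)

    def test_amplitude_stratification(self):
        evs = [SaccadeEvent(i, i + 0.1, a, 10.0, 100) for i, a in enumerate((3.5, 5.0, 9.0))]
        strata = bin_directions(evs, 9.0, min_amplitudes=(3.0, 4.5, 6.0))
        assert strata[3.0].sum() == 3 and strata[4.5].sum() == 2 and strata[6.0].sum() == 1

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            bin_directions([], 7.0)

    @pytest.mark.parametrize(
        "amps_a,amps_b,expected",
        [([4.0], [6.0], 5.0), ([], [6.0, 8.0], 7.0), ([2.5, 2.5], [2.5], 2.5)],
    )
    def test_mean_amplitude_across_staircases(self, amps_a, amps_b, expected):
        mk = lambda amps, off: [SaccadeEvent(off + i, off + i + 0.05, a, 0, 100)
                                for i, a in enumerate(amps)]
        assert mean_saccade_amplitude((mk(amps_a, 0), mk(amps_b, 100))) == pytest.approx(expected)

    def test_no_saccades_anywhere_is_missing(self):
        assert math.isnan(mean_saccade_amplitude(([], [])))


def test_session_median_positive_on_moving_gaze():
    g = _drifting_trace_with_saccade()
    assert session_median(compute_velocity(g)) > 0
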