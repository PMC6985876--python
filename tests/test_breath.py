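import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioresp.breath import (
    BreathSeries,
    detect_events,
    event_summary,
    poincare_stats,
    segment_breaths,
    ventilation_summary,
)
from cardioresp.core_io import AnnotationTable, SignalTrace
from cardioresp.synth import SynthConfig, generate_breathing

from conftest import EUPNEA_KW, match_events


def make_series(intervals, vts, body_mass=300.0, ti_frac=0.4, gaps=None):
    """Construct a BreathSeries from onset-to-onset intervals and VTs.

    ``gaps`` maps breath index -> silent pause inserted after that breath.
    """
    gaps = gaps or {}
    onsets, ends = [], []
    t = 0.0
    for i, iv in enumerate(intervals):
        onsets.append(t)
        ends.append(t + iv)
        t += iv + gaps.get(i, 0.0)
    onsets = np.array(onsets)
    ends = np.array(ends)
    interval = np.append(np.diff(onsets), intervals[-1])
    return BreathSeries(
        onsets=onsets,
        exp_onsets=onsets + ti_frac * np.asarray(intervals),
        ends=ends,
        vt=np.asarray(vts, dtype=float),
        interval=interval,
        body_mass=body_mass,
    )


class TestSegmentBreaths:
    def test_eupnea_count_60s(self):
        cfg = SynthConfig(duration=63, seed=21, rf=85.0, interval_jitter_sd=5.0, **EUPNEA_KW)
        flow, _ = generate_breathing(cfg)
        series = segment_breaths(flow, cfg.body_mass)
        n_in_60 = int(np.sum(series.onsets < 60.0))
        assert 83 <= n_in_60 <= 86

    def test_half_sine_vt_analytic(self):
        # inspiratory half-sine amplitude A, duration ti integrates to 2 A ti / pi
        fs, ti, te, amp = 1000.0, 0.3, 0.4, 5.0
        cycle = np.zeros(int((ti + te) * fs))
        n_i = int(ti * fs)
        cycle[:n_i] = amp * np.sin(np.pi * np.arange(n_i) / (ti * fs))
        cycle[n_i:] = -1.2
        flow = SignalTrace(np.tile(cycle, 5), fs, units="mL/s")
        series = segment_breaths(flow, 300.0)
        expected = 2 * amp * ti / np.pi
        np.testing.assert_allclose(series.vt, expected, rtol=2e-3)

    def test_flat_signal_rejected(self):
        with pytest.raises(ValueError, match="no breaths"):
            segment_breaths(SignalTrace(np.zeros(1000), 100.0, units="mL/s"), 300.0)

    def test_breath_ordering_invariants(self, eupnea):
        _, _, series = eupnea
        assert np.all(series.onsets < series.exp_onsets)
        assert np.all(series.exp_onsets < series.ends)
        assert np.all(np.diff(series.onsets) > 0)

    def test_onsets_match_truth_spacing(self, eupnea, eupnea_cfg):
        _, _, series = eupnea
        assert np.mean(series.interval) == pytest.approx(60.0 / eupnea_cfg.rf, rel=0.02)


class TestVentilationSummary:
    def test_worked_example(self):
        series = make_series([1.0] * 10, [0.93] * 10)
        summary = ventilation_summary(series, (0.0, 10.0))
        assert summary.vt_per100g == pytest.approx(0.31)
        assert summary.rf == pytest.approx(60.0)
        assert summary.ve == pytest.approx(18.6)

    def test_ve_identity_exact(self, eupnea):
        flow, _, series = eupnea
        summary = ventilation_summary(series, (0.0, flow.duration))
        assert summary.ve == summary.vt_per100g * summary.rf

    def test_body_mass_scaling(self):
        s1 = make_series([1.0] * 10, [0.93] * 10, body_mass=300.0)
        s2 = make_series([1.0] * 10, [0.93] * 10, body_mass=600.0)
        v1 = ventilation_summary(s1, (0.0, 10.0))
        v2 = ventilation_summary(s2, (0.0, 10.0))
        assert v2.vt_per100g == pytest.approx(v1.vt_per100g / 2)
        assert v2.ve == pytest.approx(v1.ve / 2)

    def test_ten_second_convention_flags(self):
        s13 = make_series([10.0 / 13.0] * 13, [1.0] * 13)
        assert not ventilation_summary(s13, (0.0, 10.0), ten_second_convention=True).valid
        s10 = make_series([1.0] * 10, [1.0] * 10)
        assert ventilation_summary(s10, (0.0, 10.0), ten_second_convention=True).valid

    def test_empty_window_rejected(self):
        series = make_series([1.0] * 10, [1.0] * 10)
        with pytest.raises(ValueError):
            ventilation_summary(series, (5.0, 5.0))


class TestDetectEvents:
    def test_constant_eupnea_empty(self):
        series = make_series([0.7] * 60, [1.0] * 60)
        assert len(detect_events(series)) == 0

    def test_threshold_boundary_hypopnea(self):
        vts = [1.0] * 60
        vts[30] = 0.49
        events = detect_events(make_series([0.7] * 60, vts))
        assert len(events.of_kind("hypopnea")) == 1
        vts[30] = 0.51
        assert len(detect_events(make_series([0.7] * 60, vts))) == 0

    def test_sigh_threshold(self):
        vts = [1.0] * 60
        vts[40] = 1.51
        events = detect_events(make_series([0.7] * 60, vts))
        assert len(events.of_kind("sigh")) == 1

    def test_constructed_apneas_and_hypopneas(self):
        vts = [1.0] * 200
        for i in (120, 150):
            vts[i] = 0.4
        gaps = {50: 2.5, 80: 2.8, 100: 2.6, 170: 3.0}  # >= 3 x 0.7 s cycles
        series = make_series([0.7] * 200, vts, gaps=gaps)
        events = detect_events(series)
        apneas = events.of_kind("apnea")
        hypos = events.of_kind("hypopnea")
        assert len(apneas) == 4 and len(hypos) == 2
        truth_apnea_onsets = [series.ends[i] for i in (50, 80, 100, 170)]
        tp, fn, fp = match_events(truth_apnea_onsets, [e.onset for e in apneas], tol=0.7)
        assert fn == 0 and fp == 0

    def test_post_sigh_apnea_classification(self):
        vts = [1.0] * 100
        vts[50] = 1.8
        series = make_series([0.7] * 100, vts, gaps={50: 2.5})
        events = detect_events(series)
        assert len(events.of_kind("post_sigh_apnea")) == 1
        assert len(events.of_kind("apnea")) == 0

    def test_generated_recording_recovery(self, hour_recording):
        cfg, flow, truth, series = hour_recording
        events = detect_events(series)
        cycle = 60.0 / cfg.rf
        for kind in ("apnea", "hypopnea", "sigh", "post_sigh_apnea"):
            tp, fn, fp = match_events(truth.onsets(kind), events.onsets(kind), tol=cycle)
            n = len(truth.of_kind(kind))
            if n:
                assert tp / n >= 0.9, kind

    def test_too_few_breaths_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            detect_events(make_series([0.7] * 5, [1.0] * 5))


class TestEventSummary:
    def test_worked_example(self):
        table = AnnotationTable()
        for k in range(4):
            table.add("apnea", 100.0 * k + 10, 2.5)
        for k in range(2):
            table.add("hypopnea", 300.0 * k + 50, 0.7)
        summary = event_summary(table, 1800.0)
        assert summary.apnea_rate == pytest.approx(8.0)
        assert summary.hypopnea_rate == pytest.approx(4.0)
        assert summary.ahi == pytest.approx(12.0)
        assert summary.mean_durations["apnea"] == pytest.approx(2.5)

    def test_empty_table(self):
        summary = event_summary(AnnotationTable(), 600.0)
        assert summary.ahi == 0.0
        assert summary.mean_durations == {}

    def test_duration_scaling(self):
        table = AnnotationTable()
        table.add("sigh", 5.0, 0.7)
        assert event_summary(table, 3600.0).sigh_rate == pytest.approx(
            2 * event_summary(table, 7200.0).sigh_rate
        )

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            event_summary(AnnotationTable(), -1.0)


def poincare_oracle(x):
    """Independent lag-plot rotation oracle for SD1 plus the ellipse identity.

    Points (x_i, x_{i+1}) are rotated by -45 degrees with an explicit
    rotation matrix; SD1 is the population SD along the rotated minor
    axis, SD2 follows from SD1^2 + SD2^2 = 2 Var(x).
    """
    x = np.asarray(x, dtype=float)
    pts = np.stack([x[:-1], x[1:]])
    c, s = math.cos(math.pi / 4), math.sin(math.pi / 4)
    rot = np.array([[c, s], [-s, c]]) @ pts
    sd1 = float(np.std(rot[1]))
    sd2_sq = 2.0 * float(np.var(x)) - sd1 * sd1
    return sd1, math.sqrt(max(sd2_sq, 0.0))


class TestPoincare:
    def test_constant_intervals_zero(self):
        stats = poincare_stats(make_series([0.7] * 300, [1.0] * 300), n=300)
        assert stats.sd1 == pytest.approx(0.0, abs=1e-9)
        assert stats.sd2 == pytest.approx(0.0, abs=1e-9)

    def test_alternating_closed_form(self):
        # 301 intervals give an even number of lag-1 differences, so the
        # +/-100 ms alternation has exactly zero mean and SD1 = 100/sqrt(2)
        iv = ([0.3, 0.4] * 150) + [0.3]
        stats = poincare_stats(make_series(iv, [1.0] * 301), n=301)
        assert stats.sd1 == pytest.approx(100.0 / math.sqrt(2), abs=1e-6)
        assert stats.sd2 == pytest.approx(0.0, abs=1e-3)

    def test_iid_gaussian(self, rng):
        sigma = 40.0
        iv = 0.7 + rng.normal(0, sigma / 1000.0, size=300)
        stats = poincare_stats(make_series(iv, [1.0] * 300), n=300)
        assert stats.sd1 == pytest.approx(sigma, rel=0.05)
        assert stats.sd2 == pytest.approx(sigma, rel=0.05)

    def test_matches_rotation_oracle(self, rng):
        for _ in range(20):
            iv = 0.7 + rng.normal(0, 0.05, size=300)
            stats = poincare_stats(make_series(iv, [1.0] * 300), n=300)
            sd1_o, sd2_o = poincare_oracle(iv * 1000.0)
            assert stats.sd1 == pytest.approx(sd1_o, abs=1e-9)
            assert stats.sd2 == pytest.approx(sd2_o, abs=1e-9)

    def test_ellipse_identity(self, rng):
        iv = 0.7 + rng.normal(0, 0.03, size=300)
        stats = poincare_stats(make_series(iv, [1.0] * 300), n=300)
        var_x = np.var(iv * 1000.0)
        assert stats.sd1**2 + stats.sd2**2 == pytest.approx(2 * var_x, rel=1e-9)

    def test_cv_vt(self, rng):
        vts = np.exp(rng.normal(0, 0.1, size=300))
        stats = poincare_stats(make_series([0.7] * 300, vts), n=300)
        assert stats.cv_vt == pytest.approx(100 * np.std(vts) / np.mean(vts), rel=1e-9)

    def test_too_few_breaths(self):
        with pytest.raises(ValueError, match="300"):
            poincare_stats(make_series([0.7] * 100, [1.0] * 100), n=300)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.3, 2.0), min_size=20, max_size=80))
    def test_identity_property(self, iv):
        stats = poincare_stats(make_series(iv, [1.0] * len(iv)), n=len(iv))
        var_x = np.var(np.asarray(iv) * 1000.0)
        assert stats.sd1**2 + stats.sd2**2 == pytest.approx(2 * var_x, rel=1e-6, abs=1e-6)
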