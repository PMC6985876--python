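import numpy as np
import pytest

from cardioresp.breath import segment_breaths, ventilation_summary
from cardioresp.core_io import GasProtocol, GasSegment
from cardioresp.hemo import BeatSeries
from cardioresp.hrv import band_powers, build_tachogram, psd_ar
from cardioresp.synth import (
    SynthConfig,
    generate_beat_times,
    generate_breathing,
    generate_chemo_session,
    generate_pressure,
    jitter_sd_for_sd2,
    vt_cv_to_sigma,
)

from conftest import EUPNEA_KW


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SynthConfig(rf=0)
        with pytest.raises(ValueError):
            SynthConfig(interval_ar1=1.0)
        with pytest.raises(ValueError):
            SynthConfig(lf_mod_freq=1.0)
        with pytest.raises(ValueError):
            SynthConfig(sbp=80, dbp=90)

    def test_round_trip_dict(self):
        cfg = SynthConfig(seed=9, apnea_rate=2.0)
        assert SynthConfig.from_dict(cfg.to_dict()) == cfg

    def test_vt_ml(self):
        assert SynthConfig(vt=0.32, body_mass=300).vt_ml == pytest.approx(0.96)

    def test_jitter_mapping(self):
        # SD2 = sd * sqrt(1 + phi) under AR(1)
        assert jitter_sd_for_sd2(71.5, 0.0) == pytest.approx(71.5)
        assert jitter_sd_for_sd2(50.0, 1.0) == pytest.approx(50.0 / np.sqrt(2))

    def test_cv_mapping(self):
        sigma = vt_cv_to_sigma(20.0)
        assert np.sqrt(np.exp(sigma**2) - 1) == pytest.approx(0.2)


class TestGenerateBreathing:
    def test_determinism(self):
        cfg = SynthConfig(duration=120, seed=11)
        f1, t1 = generate_breathing(cfg)
        f2, t2 = generate_breathing(cfg)
        np.testing.assert_array_equal(f1.samples, f2.samples)
        assert t1 == t2

    def test_no_events_empty_truth(self, eupnea):
        _, truth, _ = eupnea
        assert len(truth) == 0

    def test_truth_events_before_duration(self, hour_recording):
        cfg, _, truth, _ = hour_recording
        for ev in truth:
            assert ev.onset + ev.duration <= cfg.duration + 1e-9

    def test_apnea_count_poisson(self):
        # 0.5-h recordings at 24 events/h: mean truth count over 150 seeds
        # should fall inside the 95% CI of the Poisson mean (12)
        counts = []
        for seed in range(150):
            cfg = SynthConfig(
                duration=1800, seed=seed, flow_rate=25, noise_sd_flow=0.0,
                apnea_rate=24.0, hypopnea_rate=0.0, sigh_rate=0.0,
            )
            _, truth = generate_breathing(cfg)
            counts.append(len(truth.of_kind("apnea")))
        mean = np.mean(counts)
        half = 1.96 * np.sqrt(12.0 / len(counts))
        assert abs(mean - 12.0) <= half

    def test_truth_consistency_apnea_flow_silent(self):
        cfg = SynthConfig(duration=900, seed=5, noise_sd_flow=0.0, apnea_rate=20.0,
                          hypopnea_rate=0.0, sigh_rate=0.0)
        flow, truth = generate_breathing(cfg)
        theta = 0.05 * np.percentile(np.abs(flow.samples), 95)
        fs = flow.sampling_rate
        apneas = truth.of_kind("apnea")
        assert apneas
        for ev in apneas:
            i0 = int(np.ceil(ev.onset * fs)) + 1
            i1 = int(np.floor((ev.onset + ev.duration) * fs)) - 1
            assert np.all(np.abs(flow.samples[i0:i1]) < theta)

    def test_overlapping_rates_rejected(self):
        with pytest.raises(ValueError, match="too high"):
            generate_breathing(SynthConfig(duration=600, apnea_rate=3000.0))

    def test_eupneic_rate_and_vt(self, eupnea, eupnea_cfg):
        flow, _, series = eupnea
        vent = ventilation_summary(series, (0.0, flow.duration))
        assert vent.rf == pytest.approx(eupnea_cfg.rf, rel=0.03)
        assert vent.vt_per100g == pytest.approx(eupnea_cfg.vt, rel=0.05)


class TestGeneratePressure:
    def test_constant_rate_no_modulation(self):
        cfg = SynthConfig(duration=30, seed=0, hr=300, lf_mod_depth=0.0,
                          hf_mod_depth=0.0, rr_noise_ms=0.0)
        times = generate_beat_times(cfg)
        np.testing.assert_allclose(np.diff(times), 0.2, atol=1e-12)

    def test_pressure_bounds(self):
        cfg = SynthConfig(duration=20, seed=0, noise_sd_pressure=0.0)
        trace = generate_pressure(cfg)
        assert trace.sampling_rate == 500.0
        assert trace.samples.max() == pytest.approx(cfg.sbp, abs=0.5)
        assert trace.samples.min() == pytest.approx(cfg.dbp, abs=0.5)

    def test_requires_breathing_when_coupled(self):
        cfg = SynthConfig(duration=20, coupling_gain=5.0)
        with pytest.raises(ValueError, match="requires a breathing signal"):
            generate_pressure(cfg)

    def test_hf_only_modulation_lands_in_hf_band(self):
        cfg = SynthConfig(duration=660, seed=4, lf_mod_depth=0.0, hf_mod_depth=6.0,
                          rr_noise_ms=0.2)
        beats = BeatSeries.from_times(generate_beat_times(cfg))
        tacho = build_tachogram(beats)
        summary = band_powers(psd_ar(tacho, window_s=600, subwindow_s=60))
        assert summary.hf_nu > 90.0

    def test_coupled_sbp_tracks_vt(self, eupnea, eupnea_cfg):
        flow, _, series = eupnea
        cfg = SynthConfig(**{**eupnea_cfg.to_dict(), "duration": 60.0,
                             "coupling_gain": 10.0, "noise_sd_pressure": 0.0,
                             "apnea_cycles": eupnea_cfg.apnea_cycles})
        trace = generate_pressure(cfg, series)
        # systolic excursions must exceed the uncoupled pulse ceiling
        assert trace.samples.max() > cfg.sbp + 0.5


class TestChemoSession:
    @staticmethod
    def _protocol(fico2=7.0, t_each=300.0):
        return GasProtocol((
            GasSegment(0.0, t_each, 21.0, 0.03),
            GasSegment(t_each, 2 * t_each, 21.0, fico2),
        ))

    def test_normoxia_stationary(self):
        protocol = GasProtocol((GasSegment(0.0, 600.0, 21.0, 0.03),))
        cfg = SynthConfig(duration=600, seed=3, **EUPNEA_KW)
        bundle, _ = generate_chemo_session(cfg, protocol)
        series = segment_breaths(bundle.flow, cfg.body_mass)
        early = ventilation_summary(series, (30.0, 150.0)).ve
        late = ventilation_summary(series, (450.0, 570.0)).ve
        assert late == pytest.approx(early, rel=0.05)

    def test_hypercapnic_plateau_matches_gain(self):
        gain = 5.0
        cfg = SynthConfig(duration=600, seed=8, hcvr_gain=gain, resp_tau=20.0, **EUPNEA_KW)
        bundle, _ = generate_chemo_session(cfg, self._protocol())
        series = segment_breaths(bundle.flow, cfg.body_mass)
        baseline = ventilation_summary(series, (120.0, 280.0)).ve
        plateau = ventilation_summary(series, (480.0, 590.0)).ve
        # asymptotic delta VE = gain * (7 - 0.03), first-order response settled
        assert plateau - baseline == pytest.approx(gain * 6.97, rel=0.07)

    def test_gain_monotonicity(self):
        plateaus = []
        for gain in (2.0, 6.0):
            cfg = SynthConfig(duration=600, seed=2, hcvr_gain=gain, resp_tau=20.0, **EUPNEA_KW)
            bundle, _ = generate_chemo_session(cfg, self._protocol())
            series = segment_breaths(bundle.flow, cfg.body_mass)
            plateaus.append(ventilation_summary(series, (480.0, 590.0)).ve)
        assert plateaus[0] < plateaus[1]

    def test_empty_protocol_rejected(self):
        with pytest.raises(ValueError):
            GasProtocol(())
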