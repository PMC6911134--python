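"""Breath segmentation, breathing pattern, trigger/PEEPi/P0.1 metrics."""

from dataclasses import replace

import numpy as np
import pytest

from weanlab.errors import AnalysisError
from weanlab.simulate import SimConfig, ps_settings, simulate_record
from weanlab.waveforms import (Breath, WaveformRecord, breathing_pattern,
                               detect_occlusions, intrinsic_peep, p01,
                               segment_breaths, trigger_metrics,
                               ventilator_pressures)


def _record(flow, paw=None, pes=None, fs=200.0):
    n = len(flow)
    return WaveformRecord(
        time=np.arange(n) / fs, flow=np.asarray(flow, float),
        paw=np.full(n, 5.0) if paw is None else np.asarray(paw, float),
        pes=pes if pes is None else np.asarray(pes, float),
        sampling_rate=fs)


class TestSegmentation:
    def test_sine_flow_counts_periods(self, sine_record):
        breaths = segment_breaths(sine_record)
        assert len(breaths) == 15
        # symmetric sine: Ti ~ Te ~ 2 s, VT = integral of the half wave
        vt_expected = 0.5 * 2.0 / (np.pi * 0.25 * 2.0)
        for b in breaths:
            assert b.vt == pytest.approx(vt_expected, rel=0.01)
            assert b.ti == pytest.approx(2.0, abs=0.05)

    def test_apneic_record_empty(self):
        assert segment_breaths(_record(np.zeros(2000))) == []

    def test_simulated_rate_recovered(self, ps_record):
        rec, _ = ps_record
        pattern = breathing_pattern(segment_breaths(rec), rec)
        assert pattern.rr == pytest.approx(25.0, abs=1.0)

    def test_idempotent(self, ps_record):
        rec, _ = ps_record
        a = segment_breaths(rec)
        b = segment_breaths(rec)
        assert [(x.flow_onset_idx, x.end_insp_idx) for x in a] == \
               [(x.flow_onset_idx, x.end_insp_idx) for x in b]

    def test_volume_conservation(self, ps_record):
        # no leak modeled: inspired and expired volumes balance within 5%
        rec, _ = ps_record
        breaths = segment_breaths(rec)
        insp = sum(b.vt for b in breaths)
        fs = rec.sampling_rate
        exp = -sum(np.trapezoid(np.minimum(
            rec.flow[b.end_insp_idx:b.end_exp_idx + 1], 0.0), dx=1 / fs)
            for b in breaths)
        assert insp == pytest.approx(exp, rel=0.05)


class TestBreathingPattern:
    def test_square_breath_volume(self):
        fs = 200.0
        flow = np.concatenate([np.zeros(100), np.full(200, 0.5),
                               np.full(300, -1 / 3), np.zeros(200),
                               np.full(200, 0.5), np.full(300, -1 / 3),
                               np.zeros(100)])
        breaths = segment_breaths(_record(flow), occlusions=[])
        assert len(breaths) >= 1
        assert breaths[0].vt == pytest.approx(0.5, abs=0.01)

    def test_ratios_consistent_on_uniform_breaths(self, sine_record):
        pattern = breathing_pattern(segment_breaths(sine_record), sine_record)
        assert pattern.rr_over_vt == pytest.approx(pattern.rr / pattern.vt,
                                                   rel=0.01)
        assert pattern.minute_ventilation == pytest.approx(
            pattern.vt * pattern.rr, rel=0.01)
        assert pattern.ti_te_ratio == pytest.approx(pattern.ti / pattern.te,
                                                    rel=0.02)

    def test_rsbi_at_study_medians(self):
        # RR 27 / VT 0.35 l = 77 breaths/min/l, the ATC-arm median ratio
        assert 27.0 / 0.35 == pytest.approx(77.0, abs=0.2)

    def test_empty_raises(self, sine_record):
        with pytest.raises(AnalysisError):
            breathing_pattern([], sine_record)


class TestTriggerMetrics:
    def test_no_dip_flagged_zero(self, sine_record):
        b = segment_breaths(sine_record)[1]
        dp, dt = trigger_metrics(sine_record, b)
        assert (dp, dt) == (0.0, 0.0)

    def test_simulated_valve_delay(self, patient):
        cfg = SimConfig(duration=60.0, seed=4, pes_noise_sd=0.0,
                        cardiac_artifact_amplitude=0.0, n_occlusions=0)
        p = replace(patient, intrinsic_peep=0.3)
        rec, _ = simulate_record(
            p, ps_settings(peep=4.0, ps=7.0, valve_delay=0.15), cfg)
        breaths = segment_breaths(rec)
        dts = [trigger_metrics(rec, b, peep=4.0)[1] for b in breaths]
        # effort onset -> Paw back at PEEP: valve delay plus the short
        # trigger-crossing and repressurisation intervals
        assert 0.15 <= np.median(dts) <= 0.27

    def test_dip_depth_tracks_circuit_resistance(self, patient):
        cfg = SimConfig(duration=60.0, seed=4, pes_noise_sd=0.0,
                        cardiac_artifact_amplitude=0.0, n_occlusions=0)
        rec, _ = simulate_record(
            patient, ps_settings(trigger_resistance=20.0), cfg)
        rec2, _ = simulate_record(
            patient, ps_settings(trigger_resistance=5.0), cfg)
        dp_hi = ventilator_pressures(rec, segment_breaths(rec)).dp_trig
        dp_lo = ventilator_pressures(rec2, segment_breaths(rec2)).dp_trig
        assert dp_hi < dp_lo < 0.0


class TestIntrinsicPeep:
    def test_direct_definition(self):
        fs = 200.0
        n = 800
        pes = np.full(n, 10.0)
        pes[300:400] = np.linspace(10.0, 8.0, 100)   # 2 cmH2O fall pre-flow
        pes[400:600] = 8.0
        flow = np.zeros(n)
        flow[400:600] = 0.5
        rec = _record(flow, pes=pes)
        b = Breath(effort_onset_idx=300, flow_onset_idx=400, end_insp_idx=599,
                   end_exp_idx=799, vt=0.5, ti=1.0, te=1.0)
        assert intrinsic_peep(rec, b) == pytest.approx(2.0)

    def test_simultaneous_onsets_zero(self, sine_record):
        b = Breath(effort_onset_idx=100, flow_onset_idx=100, end_insp_idx=300,
                   end_exp_idx=500, vt=0.4, ti=1.0, te=1.0)
        assert intrinsic_peep(sine_record, b) == 0.0

    def test_simulated_peepi_recovered(self, patient):
        p = replace(patient, intrinsic_peep=3.0)
        cfg = SimConfig(duration=60.0, seed=5, pes_noise_sd=0.0,
                        cardiac_artifact_amplitude=0.0, n_occlusions=0)
        rec, _ = simulate_record(p, ps_settings(), cfg)
        vals = [intrinsic_peep(rec, b) for b in segment_breaths(rec)]
        assert np.median(vals) == pytest.approx(3.0, abs=0.3)


class TestOcclusions:
    def test_ramp_occlusion_p01(self):
        # occluded Pmus ramp of 30 cmH2O/s drops Paw by 3.0 in 100 ms
        fs = 200.0
        n = 1000
        paw = np.full(n, 10.0)
        ramp = np.arange(120) / fs * 30.0
        paw[600:720] = 10.0 - ramp
        paw[720:] = paw[719]
        rec = _record(np.zeros(n), paw=paw)
        events = detect_occlusions(rec)
        assert len(events) == 1
        assert events[0].p01 == pytest.approx(3.0, abs=0.05)

    def test_five_equal_events_average(self):
        assert np.mean([3.3] * 5) == pytest.approx(3.3)

    def test_no_events_absent(self, sine_record):
        assert p01(sine_record) is None

    def test_simulated_events_detected_and_exact(self, ps_record):
        rec, gt = ps_record
        events = detect_occlusions(rec)
        assert len(events) == len(gt.occlusion_onsets)
        for ev, j_true in zip(events, sorted(gt.occlusion_onsets)):
            assert abs(ev.onset_idx - j_true) <= 1
            # occlusion contract: measured drop == Pmus rise on the same span
            truth = gt.pmus[ev.onset_idx + 20] - gt.pmus[ev.onset_idx]
            assert ev.p01 == pytest.approx(truth, abs=1e-6)

    def test_p01_against_ground_truth_slopes(self, ps_record):
        rec, gt = ps_record
        measured = p01(rec)
        assert measured == pytest.approx(float(np.mean(gt.occlusion_p01)),
                                         rel=0.05)


class TestVentilatorPressures:
    def test_constant_paw(self, sine_record):
        vm = ventilator_pressures(sine_record, segment_breaths(sine_record))
        assert vm.peep_measured == pytest.approx(5.0)
        assert vm.max_insp_pressure == pytest.approx(5.0)

    def test_ps_maxima_and_peep(self, patient):
        cfg = SimConfig(duration=60.0, seed=6, pes_noise_sd=0.0,
                        cardiac_artifact_amplitude=0.0, n_occlusions=0)
        rec, _ = simulate_record(
            patient, ps_settings(peep=5.0, ps=7.0, rise_time_constant=0.005),
            cfg)
        breaths = segment_breaths(rec)
        assert len(breaths) >= 20
        vm = ventilator_pressures(rec, breaths)
        assert vm.peep_measured == pytest.approx(5.0, abs=0.1)
        assert round(vm.max_insp_pressure) == 12
        assert vm.max_insp_flow == pytest.approx(np.max(rec.flow), rel=0.05)
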