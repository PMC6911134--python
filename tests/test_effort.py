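"""Chest wall, Pmus reconstruction, Campbell decomposition, powers."""

import numpy as np
import pytest

from weanlab.effort import (EffortBreath, campbell_decomposition,
                            chest_wall_elastance, effort_summary,
                            pmus_waveform, predicted_vc)
from weanlab.errors import AnalysisError, ParameterError
from weanlab.waveforms import Breath, WaveformRecord, segment_breaths


class TestChestWall:
    def test_reference_equation_male(self):
        # 6.10*h - 0.028*a - 4.65 at 60 y, 1.75 m
        assert predicted_vc("male", 60, 1.75) == pytest.approx(4.345)

    def test_female_smaller_than_male(self):
        assert predicted_vc("female", 60, 1.75) < predicted_vc("male", 60, 1.75)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            predicted_vc("male", 15, 1.75)
        with pytest.raises(ParameterError):
            predicted_vc("male", 60, 2.5)

    @pytest.mark.parametrize("vc,expected", [(5.0, 5.0), (2.5, 10.0)])
    def test_elastance_reciprocal_convention(self, vc, expected):
        assert chest_wall_elastance(vc) == pytest.approx(expected)

    def test_doubling_vc_halves_elastance(self):
        assert chest_wall_elastance(6.0) == pytest.approx(
            chest_wall_elastance(3.0) / 2.0)

    def test_literal_mode_needs_delta_pes(self):
        with pytest.raises(ParameterError):
            chest_wall_elastance(5.0, mode="pes_over_4pct_vc")
        assert chest_wall_elastance(5.0, delta_pes=2.0,
                                    mode="pes_over_4pct_vc") == pytest.approx(10.0)


def _ramp_record(ecw=4.0, vt=0.5, pes_drop=10.0, fs=200.0):
    """1 s inspiration with linear Pes fall and constant flow, then expiration.

    201 inspiratory samples so trapezoid integration of the constant flow
    gives exactly ``vt`` at the window end.
    """
    ni = int(fs) + 1
    ne = 2 * int(fs) - 1
    flow = np.concatenate([np.full(ni, vt), np.full(ne // 2, -vt),
                           np.zeros(ne - ne // 2)])
    pes = np.concatenate([np.linspace(0.0, -pes_drop, ni), np.zeros(ne)])
    n = ni + ne
    rec = WaveformRecord(time=np.arange(n) / fs, flow=flow,
                         paw=np.full(n, 5.0), pes=pes, sampling_rate=fs)
    breath = Breath(effort_onset_idx=0, flow_onset_idx=0,
                    end_insp_idx=ni - 1, end_exp_idx=n - 1,
                    vt=vt, ti=1.0, te=2.0)
    return rec, breath


class TestPmusWaveform:
    def test_relaxation_line_gives_zero(self):
        fs = 200.0
        n = 600
        flow = np.concatenate([np.full(200, 0.4), np.full(200, -0.4),
                               np.zeros(200)])
        v = np.concatenate([[0.0], np.cumsum((flow[1:] + flow[:-1]) / 2) / fs])
        pes = 8.0 + 5.0 * v          # Pes exactly on the recoil line
        rec = WaveformRecord(time=np.arange(n) / fs, flow=flow,
                             paw=np.full(n, 5.0), pes=pes, sampling_rate=fs)
        b = Breath(0, 0, 199, 599, vt=0.4, ti=1.0, te=2.0)
        assert np.max(np.abs(pmus_waveform(rec, b, 5.0))) < 1e-9

    def test_substitution_example(self):
        # ecw 5, V 0.4 l, Pes fell 0 -> -8: Pmus = 5*0.4 + 8 = 10
        rec, b = _ramp_record(ecw=5.0, vt=0.4, pes_drop=8.0)
        pm = pmus_waveform(rec, b, 5.0)
        assert pm[-1] == pytest.approx(10.0, rel=1e-3)

    def test_missing_pes_rejected(self):
        rec, b = _ramp_record()
        rec.pes = None
        with pytest.raises(AnalysisError):
            pmus_waveform(rec, b, 4.0)

    def test_noise_free_recovery_matches_ground_truth(self, ps_record):
        rec, gt = ps_record
        breaths = segment_breaths(rec)
        assert len(breaths) >= 20
        # skip the record's opening breath: no Pes history precedes it, so
        # the effort onset cannot be located there
        for b in breaths[1:21]:
            pm = pmus_waveform(rec, b, gt.ecw)
            truth = gt.pmus[b.effort_onset_idx:b.end_insp_idx + 1]
            assert np.max(np.abs(pm - truth)) < 0.1


class TestCampbell:
    def test_linear_loop_closed_form(self):
        # Pes ramp 0 -> -10 over V 0 -> 0.5, ecw 4: Pmus = 24V,
        # total = int 24V dV = 3.0 cmH2O*l = 0.294 J, all elastic
        rec, b = _ramp_record(ecw=4.0, vt=0.5, pes_drop=10.0)
        eb = campbell_decomposition(rec, b, 4.0)
        assert eb.wob_total == pytest.approx(3.0 * 0.0980665, rel=1e-6)
        assert eb.wob_elastic == pytest.approx(3.0 * 0.0980665, rel=1e-6)
        assert eb.wob_resistive == pytest.approx(0.0, abs=1e-9)

    def test_zero_effort_all_zero(self):
        fs = 200.0
        n = 600
        flow = np.concatenate([np.full(200, 0.4), np.full(200, -0.4),
                               np.zeros(200)])
        v = np.concatenate([[0.0], np.cumsum((flow[1:] + flow[:-1]) / 2) / fs])
        pes = 8.0 + 5.0 * v
        rec = WaveformRecord(time=np.arange(n) / fs, flow=flow,
                             paw=np.full(n, 5.0), pes=pes, sampling_rate=fs)
        b = Breath(0, 0, 199, 599, vt=0.4, ti=1.0, te=2.0)
        eb = campbell_decomposition(rec, b, 5.0)
        assert eb.wob_total == pytest.approx(0.0, abs=1e-9)
        assert eb.wob_elastic == pytest.approx(0.0, abs=1e-9)

    def _shoelace_oracle(self, rec, b, ecw):
        """Independent polygon-area computation of the Campbell areas."""
        fs = rec.sampling_rate
        seg = rec.flow[b.effort_onset_idx:b.end_insp_idx + 1]
        v = np.concatenate([[0.0],
                            np.cumsum((seg[1:] + seg[:-1]) / 2.0) / fs])
        pes = rec.pes[b.effort_onset_idx:b.end_insp_idx + 1]
        relax = pes[0] + ecw * v
        # closed polygon: measured trace forward, recoil line backward
        xs = np.concatenate([v, v[::-1]])
        ys = np.concatenate([pes, relax[::-1]])
        area = 0.5 * np.sum(xs * np.roll(ys, -1) - np.roll(xs, -1) * ys)
        total = area  # positive when Pes lies below the recoil line
        i_fo = b.flow_onset_idx - b.effort_onset_idx
        chord_lo, chord_hi = pes[i_fo], pes[-1]
        st_lo, st_hi = pes[0] + ecw * v[i_fo], pes[0] + ecw * v[-1]
        elastic = (v[-1] - v[i_fo]) * ((st_lo + st_hi) / 2
                                       - (chord_lo + chord_hi) / 2)
        return total, elastic

    def test_decomposition_matches_shoelace_oracle(self, ps_record, atc_record):
        checked = 0
        for rec, gt in (ps_record, atc_record):
            for b in segment_breaths(rec):
                eb = campbell_decomposition(rec, b, gt.ecw)
                if eb.clamped:
                    continue
                total_o, elastic_o = self._shoelace_oracle(rec, b, gt.ecw)
                assert eb.wob_total == pytest.approx(
                    total_o * 0.0980665, rel=1e-9, abs=1e-12)
                assert eb.wob_elastic == pytest.approx(
                    elastic_o * 0.0980665, rel=1e-9, abs=1e-12)
                # exactness of the split
                assert eb.wob_elastic + eb.wob_resistive == pytest.approx(
                    eb.wob_total, abs=1e-15)
                checked += 1
        assert checked >= 50

    def test_rejects_non_positive_volume(self):
        rec, b = _ramp_record()
        bad = Breath(b.effort_onset_idx, b.flow_onset_idx, b.end_insp_idx,
                     b.end_exp_idx, vt=0.2, ti=b.ti, te=b.te)
        object.__setattr__(bad, "vt", -0.1)
        with pytest.raises(AnalysisError):
            campbell_decomposition(rec, bad, 4.0)


class TestEffortSummary:
    def _eb(self, e, r, ptp):
        return EffortBreath(pmus=np.zeros(1), wob_total=e + r, wob_elastic=e,
                            wob_resistive=r, ptp=ptp)

    def test_power_is_wob_times_rate(self):
        s = effort_summary([self._eb(0.20, 0.15, 5.0)] * 5, rr=25.0)
        assert s.power_total == pytest.approx(0.35 * 25.0)
        assert s.ptpmus == pytest.approx(125.0)

    def test_ptp_example(self):
        s = effort_summary([self._eb(0.1, 0.1, 5.0)] * 3, rr=20.0)
        assert s.ptpmus == pytest.approx(100.0)

    def test_total_is_sum_of_components(self):
        rng = np.random.default_rng(0)
        ebs = [self._eb(float(rng.uniform(0, .4)), float(rng.uniform(0, .3)),
                        float(rng.uniform(2, 8))) for _ in range(11)]
        s = effort_summary(ebs, rr=24.0)
        assert s.power_total == pytest.approx(s.power_elastic
                                              + s.power_resistive)

    def test_empty_rejected(self):
        with pytest.raises(AnalysisError):
            effort_summary([], rr=20.0)


class TestRecovery:
    def test_noise_free_power_within_5pct_of_truth(self, ps_record, patient):
        from weanlab.pipeline import analyze_record
        rec, gt = ps_record
        m = analyze_record(rec, patient=patient, window=80.0)
        truth = float(np.median(gt.wob_per_breath)) * patient.neural_rr
        assert m["power_total"] == pytest.approx(truth, rel=0.05)
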