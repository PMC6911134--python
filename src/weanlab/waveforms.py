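"""Breath segmentation and breathing-pattern / ventilator-function metrics.

Works on a :class:`WaveformRecord` (time, flow, airway pressure Paw,
esophageal pressure Pes on a uniform 200 Hz grid; inspiratory flow
positive).  Inspiration is defined by the flow signal crossing zero, with
a small hysteresis for noise robustness: a breath starts at the upward
zero crossing that precedes a sustained (>= 80 ms) excursion above
+0.05 l/s, and ends inspiration at the following downward zero crossing.
The onset of inspiratory *effort* is located on Pes: the last point at
which Pes still sits on its local baseline before the decline that leads
into the breath (decline detected at 0.5 cmH2O below the 0.5-s baseline,
then backtracked to the departure point).

Per-record metrics mirror standard SBT monitoring: tidal volume and
timing, intrinsic PEEP (Pes deflection from effort onset to first zero
flow, no gastric-pressure correction), trigger quality (DPtrig, the Paw
dip below PEEP while the demand valve is still closed; DTtrig, the delay
from effort onset until Paw is back at baseline PEEP), occlusion pressure
P0.1 (Paw drop over the first 100 ms of an end-expiratory occlusion,
averaged over the detected occlusions and reported positive), and maximal
inspiratory pressure / flow.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, IngestionError

log = logging.getLogger("weanlab")

__all__ = [
    "WaveformRecord",
    "Breath",
    "BreathingPattern",
    "VentilatorMetrics",
    "OcclusionEvent",
    "segment_breaths",
    "breathing_pattern",
    "trigger_metrics",
    "intrinsic_peep",
    "detect_occlusions",
    "p01",
    "ventilator_pressures",
]

TARGET_RATE = 200.0

# segmentation / detection thresholds (l/s, s, cmH2O)
FLOW_HYSTERESIS = 0.05
SUSTAIN_S = 0.08
MIN_TI_S = 0.15
EFFORT_DECLINE_CMH2O = 0.5
# short trailing baseline: long windows lag the passive expiratory Pes
# decay and fire before the true effort onset
EFFORT_BASELINE_S = 0.25
OCCLUSION_FLOW_THR = 0.02
OCCLUSION_MIN_S = 0.15
OCCLUSION_PAW_DECLINE = 0.5


@dataclass
class WaveformRecord:
    """Synchronised flow / Paw / Pes traces on a uniform time grid."""

    time: np.ndarray
    flow: np.ndarray
    paw: np.ndarray
    pes: Optional[np.ndarray]
    sampling_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("flow", "paw"):
            if len(getattr(self, name)) != n:
                raise IngestionError(f"channel {name} length mismatch")
        if self.pes is not None and len(self.pes) != n:
            raise IngestionError("channel pes length mismatch")
        if n >= 2 and not np.all(np.diff(self.time) > 0):
            bad = int(np.argmax(np.diff(self.time) <= 0)) + 1
            raise IngestionError(f"time not strictly increasing at sample {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.n_samples else 0.0

    def slice(self, t0: float, t1: float) -> "WaveformRecord":
        """Sub-record covering [t0, t1] (absolute times, inclusive)."""
        i0, i1 = np.searchsorted(self.time, [t0, t1])
        i1 = min(i1 + 1, self.n_samples)
        return WaveformRecord(
            time=self.time[i0:i1], flow=self.flow[i0:i1], paw=self.paw[i0:i1],
            pes=None if self.pes is None else self.pes[i0:i1],
            sampling_rate=self.sampling_rate, meta=dict(self.meta))


@dataclass(frozen=True)
class Breath:
    """Sample indices bounding one mechanical breath, with basic timing."""

    effort_onset_idx: int
    flow_onset_idx: int
    end_insp_idx: int
    end_exp_idx: int
    vt: float
    ti: float
    te: float

    def __post_init__(self) -> None:
        if not (self.effort_onset_idx <= self.flow_onset_idx
                < self.end_insp_idx < self.end_exp_idx):
            raise AnalysisError("breath indices out of order")


@dataclass(frozen=True)
class BreathingPattern:
    """Median breathing-pattern summary plus the per-breath table."""

    vt: float
    rr: float
    minute_ventilation: float
    ti: float
    te: float
    ti_te_ratio: float
    rr_over_vt: float
    per_breath: pd.DataFrame = field(repr=False, compare=False)


@dataclass(frozen=True)
class VentilatorMetrics:
    peep_measured: float
    dp_trig: float
    dt_trig: float
    max_insp_pressure: float
    max_insp_flow: float
    trigger_flagged: bool = False


@dataclass(frozen=True)
class OcclusionEvent:
    onset_idx: int
    release_idx: int
    p01: float


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of contiguous True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def _smooth(x: np.ndarray, width: int = 5) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def _effort_onset(pes: np.ndarray, flow_onset: int, fs: float) -> int:
    """Pes-based inspiratory effort onset preceding a flow onset.

    Finds the decline run (Pes more than 0.5 cmH2O below its trailing
    0.5-s baseline) that leads into the flow onset, then backtracks to the
    last sample still at the pre-decline level.  Falls back to the flow
    onset itself when no preceding decline is present.
    """
    nb = int(EFFORT_BASELINE_S * fs)
    lo = max(flow_onset - int(1.5 * fs), 0)
    if flow_onset - lo < nb + 4:
        return flow_onset
    # 75 ms boxcar: keeps the effort decline, suppresses sample noise
    ps = _smooth(pes, width=15)
    cs = np.concatenate([[0.0], np.cumsum(ps)])
    idx = np.arange(lo + nb, flow_onset + 1)
    baseline = (cs[idx] - cs[idx - nb]) / nb
    below = ps[idx] < baseline - EFFORT_DECLINE_CMH2O
    if not below.size or not below[-1]:
        return flow_onset
    k = below.size - 1
    while k > 0 and below[k - 1]:
        k -= 1
    cross = idx[k]
    # backtrack to the departure from the (robust) trailing baseline
    level = baseline[k] - 0.05
    w0 = max(cross - int(0.3 * fs), lo)
    seg = ps[w0:cross + 1]
    above = np.flatnonzero(seg >= level)
    onset = w0 + int(above[-1]) if above.size else cross
    return min(onset, flow_onset)


def _occlusion_mask(n: int, occlusions: Sequence[OcclusionEvent], fs: float,
                    pad_before: float = 0.1,
                    pad_after: float = 0.5) -> np.ndarray:
    # generous post-release padding: the occluded effort keeps running after
    # the valve reopens and triggers a truncated breath that must not count
    mask = np.zeros(n, dtype=bool)
    wb, wa = int(pad_before * fs), int(pad_after * fs)
    for ev in occlusions:
        mask[max(ev.onset_idx - wb, 0):min(ev.release_idx + wa + 1, n)] = True
    return mask


def segment_breaths(record: WaveformRecord,
                    occlusions: Optional[Sequence[OcclusionEvent]] = None,
                    min_vt: float = 0.03) -> list[Breath]:
    """Segment mechanical breaths from the flow signal.

    Breaths overlapping detected end-expiratory occlusions are discarded
    (their inspiratory effort is consumed by the maneuver).  An apneic
    record yields an empty list.
    """
    flow = record.flow
    fs = record.sampling_rate
    n = flow.size
    if occlusions is None:
        occlusions = detect_occlusions(record)
    occ_mask = _occlusion_mask(n, occlusions, fs)

    sustain = int(SUSTAIN_S * fs)
    above = flow > FLOW_HYSTERESIS
    onsets = []
    for s, e in _runs(above):
        if e - s < sustain:
            continue
        j = s
        lo = max(s - int(0.5 * fs), 0)
        while j > lo and flow[j - 1] > 0:
            j -= 1
        if j == 0 and flow[0] > FLOW_HYSTERESIS:
            continue  # record starts mid-inspiration: truncated breath
        if onsets and j - onsets[-1] < int(0.5 * fs):
            continue
        onsets.append(j)

    breaths: list[Breath] = []
    for k, onset in enumerate(onsets):
        j = onset + int(MIN_TI_S * fs)
        end_insp = -1
        while j < n:
            if flow[j] <= 0:
                look = flow[j:min(j + int(0.3 * fs), n)]
                if look.size == 0 or look.min() < -FLOW_HYSTERESIS or \
                        np.all(look < FLOW_HYSTERESIS):
                    end_insp = j
                    break
            j += 1
        if end_insp < 0:
            continue
        if k + 1 < len(onsets):
            end_exp = onsets[k + 1] - 1
        else:
            end_exp = n - 1
            if end_exp - end_insp < int(0.3 * fs):
                continue
        if end_exp <= end_insp:
            continue
        vt = float(np.trapezoid(flow[onset:end_insp + 1], dx=1.0 / fs))
        if vt < min_vt:
            log.debug("breath at sample %d discarded: VT %.3f l below "
                      "threshold", onset, vt)
            continue
        if record.pes is not None:
            eff = _effort_onset(record.pes, onset, fs)
        else:
            eff = onset
        if occ_mask[eff:end_insp + 1].any():
            log.debug("breath at sample %d discarded: overlaps occlusion",
                      onset)
            continue
        breaths.append(Breath(
            effort_onset_idx=eff, flow_onset_idx=onset, end_insp_idx=end_insp,
            end_exp_idx=end_exp, vt=vt, ti=(end_insp - onset) / fs,
            te=(end_exp - end_insp) / fs))
    return breaths


def breathing_pattern(breaths: Sequence[Breath],
                      record: WaveformRecord) -> BreathingPattern:
    """Per-breath tidal volume / timing table and its median summary."""
    if not breaths:
        raise AnalysisError("no breaths to summarise")
    rows = []
    for b in breaths:
        ttot = b.ti + b.te
        if b.ti <= 0:
            warnings.warn("zero-length inspiration skipped")
            continue
        rr = 60.0 / ttot
        rows.append({"vt": b.vt, "ti": b.ti, "te": b.te, "ttot": ttot,
                     "rr": rr, "minute_ventilation": b.vt * rr,
                     "ti_te_ratio": b.ti / b.te if b.te > 0 else np.nan,
                     "rr_over_vt": rr / b.vt})
    table = pd.DataFrame(rows)
    med = table.median()
    return BreathingPattern(
        vt=float(med["vt"]), rr=float(med["rr"]),
        minute_ventilation=float(med["minute_ventilation"]),
        ti=float(med["ti"]), te=float(med["te"]),
        ti_te_ratio=float(med["ti_te_ratio"]),
        rr_over_vt=float(med["rr_over_vt"]), per_breath=table)


def _measured_peep(record: WaveformRecord, breaths: Sequence[Breath],
                   occlusions: Sequence[OcclusionEvent]) -> float:
    """Median Paw over end-expiratory pauses (|flow| < 0.02 l/s)."""
    fs = record.sampling_rate
    occ_mask = _occlusion_mask(record.n_samples, occlusions, fs)
    samples = []
    for b in breaths:
        s = b.end_insp_idx + int(0.3 * fs)
        seg = slice(s, b.end_exp_idx + 1)
        sel = (np.abs(record.flow[seg]) < OCCLUSION_FLOW_THR) & ~occ_mask[seg]
        samples.append(record.paw[seg][sel])
    vals = np.concatenate(samples) if samples else np.empty(0)
    if vals.size == 0:
        # no pause: fall back to Paw just before each effort onset
        vals = np.concatenate([
            record.paw[max(b.effort_onset_idx - int(0.05 * fs), 0):
                       b.effort_onset_idx + 1] for b in breaths])
    return float(np.median(vals))


def trigger_metrics(record: WaveformRecord, breath: Breath,
                    peep: Optional[float] = None) -> tuple[float, float]:
    """(DPtrig, DTtrig) for one breath.

    DPtrig: most negative Paw deviation from PEEP between effort onset and
    pressurisation (reported <= 0).  DTtrig: time from effort onset until
    Paw is back at baseline PEEP.  Both 0 when Paw never dips.
    """
    fs = record.sampling_rate
    if peep is None:
        peep = float(np.median(
            record.paw[max(breath.effort_onset_idx - int(0.2 * fs), 0):
                       breath.effort_onset_idx + 1]))
    s = breath.effort_onset_idx
    e = min(breath.flow_onset_idx + int(0.4 * fs), breath.end_insp_idx)
    seg = record.paw[s:e + 1]
    imin = int(np.argmin(seg))
    dp = float(seg[imin] - peep)
    if dp > -0.1:
        return 0.0, 0.0
    back = np.flatnonzero(seg[imin:] >= peep - 0.05)
    if back.size == 0:
        return min(dp, 0.0), float((e - s) / fs)
    return min(dp, 0.0), float((imin + back[0]) / fs)


def intrinsic_peep(record: WaveformRecord, breath: Breath) -> float:
    """Pes deflection from effort onset to the first zero flow (cmH2O >= 0)."""
    if record.pes is None:
        raise AnalysisError("Pes channel required for intrinsic PEEP")
    if breath.effort_onset_idx >= breath.flow_onset_idx:
        return 0.0
    val = float(record.pes[breath.effort_onset_idx]
                - record.pes[breath.flow_onset_idx])
    if val < 0:
        warnings.warn("negative intrinsic PEEP clamped to 0")
        return 0.0
    return val


def detect_occlusions(record: WaveformRecord) -> list[OcclusionEvent]:
    """End-expiratory occlusions: zero-flow intervals with falling Paw.

    An event requires |flow| < 0.02 l/s for >= 0.15 s and a Paw decline
    > 0.5 cmH2O within the interval.  The onset is the last sample before
    the decline starts; P0.1 is the Paw drop over the following 100 ms.
    """
    fs = record.sampling_rate
    n100ms = int(round(0.1 * fs))
    events = []
    zero = np.abs(record.flow) < OCCLUSION_FLOW_THR
    for s, e in _runs(zero):
        if (e - s) / fs < OCCLUSION_MIN_S:
            continue
        paw = record.paw[s:e]
        if paw.max() - paw[-1] < OCCLUSION_PAW_DECLINE and \
                paw.max() - paw.min() < OCCLUSION_PAW_DECLINE:
            continue
        onset_rel = -1
        for k in range(paw.size - 1):
            if paw[k] - paw[k + 1] > 0.01 and \
                    paw[k + 1:].min() < paw[k] - OCCLUSION_PAW_DECLINE:
                onset_rel = k + 1   # first sample showing the occluded effort
                break
        if onset_rel < 0 or onset_rel + n100ms >= paw.size:
            continue
        drop = float(paw[onset_rel] - paw[onset_rel + n100ms])
        events.append(OcclusionEvent(onset_idx=s + onset_rel,
                                     release_idx=e - 1, p01=max(drop, 0.0)))
    return events


def p01(record: WaveformRecord,
        events: Optional[Sequence[OcclusionEvent]] = None) -> Optional[float]:
    """Mean P0.1 over the record's occlusion maneuvers (cmH2O, positive).

    Returns ``None`` when no occlusion is present: an absent measurement,
    not a zero drive.
    """
    if events is None:
        events = detect_occlusions(record)
    if not events:
        return None
    return float(np.mean([ev.p01 for ev in events]))


def ventilator_pressures(record: WaveformRecord, breaths: Sequence[Breath],
                         occlusions: Optional[Sequence[OcclusionEvent]] = None
                         ) -> VentilatorMetrics:
    """Measured PEEP, trigger metrics and inspiratory maxima (medians)."""
    if not breaths:
        raise AnalysisError("no breaths")
    if occlusions is None:
        occlusions = detect_occlusions(record)
    peep = _measured_peep(record, breaths, occlusions)
    max_p, max_q, dps, dts = [], [], [], []
    for b in breaths:
        seg = slice(b.flow_onset_idx, b.end_insp_idx + 1)
        max_p.append(record.paw[seg].max())
        max_q.append(record.flow[seg].max())
        dp, dt = trigger_metrics(record, b, peep=peep)
        dps.append(dp)
        dts.append(dt)
    flagged = all(d == 0.0 for d in dps)
    return VentilatorMetrics(
        peep_measured=peep, dp_trig=float(np.median(dps)),
        dt_trig=float(np.median(dts)),
        max_insp_pressure=float(np.median(max_p)),
        max_insp_flow=float(np.median(max_q)), trigger_flagged=flagged)
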