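"""Esophageal-pressure-derived effort: Pmus, Campbell WOB, power, PTPmus.

The Campbell diagram plots esophageal pressure against lung volume.  The
distance between the measured Pes (Pes,dyn) and the chest-wall static
recoil line (Pes,st, slope = chest-wall elastance Ecw, anchored at the
onset of inspiratory effort where the muscles are still relaxed) is the
muscular pressure Pmus.  Work of breathing (WOB) is the area swept by
Pmus over volume; the straight chord joining the two zero-flow points of
the loop splits it into an elastic part (between recoil line and chord)
and a resistive part (between chord and the measured trace).  Powers are
WOB x respiratory rate (J/min); PTPmus is the Pmus-time integral over
inspiration x respiratory rate (cmH2O*s/min).

Chest-wall elastance follows the convention that chest-wall compliance
equals 4% of the predicted vital capacity per cmH2O, i.e.
``Ecw = 1 / (0.04 * VC_pred)``; the predicted VC comes from a standard
spirometric reference equation (sex, age, height), pluggable by id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import AnalysisError, ParameterError
from .waveforms import Breath, WaveformRecord

__all__ = [
    "J_PER_CMH2O_L",
    "ChestWall",
    "EffortBreath",
    "EffortSummary",
    "predicted_vc",
    "chest_wall_elastance",
    "chest_wall_for_patient",
    "pmus_waveform",
    "campbell_decomposition",
    "effort_summary",
]

#: Joules per cmH2O*l (1 cmH2O = 98.0665 Pa; 1 l = 1e-3 m^3).
J_PER_CMH2O_L = 0.0980665

#: Reference vital-capacity equations (l); height m, age years.
VC_EQUATIONS = {
    "default": {
        "male": lambda h, a: 6.10 * h - 0.028 * a - 4.65,
        "female": lambda h, a: 4.66 * h - 0.026 * a - 3.28,
    },
}


@dataclass(frozen=True)
class ChestWall:
    ecw: float                      # cmH2O/l
    vc_predicted: float             # l
    reference_equation_id: str = "default"

    def __post_init__(self) -> None:
        if self.ecw <= 0 or self.vc_predicted <= 0:
            raise ParameterError("chest-wall parameters must be > 0")


@dataclass(frozen=True)
class EffortBreath:
    """Per-breath effort decomposition.

    ``wob_total = wob_elastic + wob_resistive`` holds exactly by
    construction; a (rare) negative total is floored at 0 and flagged.
    """

    pmus: np.ndarray = field(repr=False, compare=False)
    wob_total: float
    wob_elastic: float
    wob_resistive: float
    ptp: float
    clamped: bool = False


@dataclass(frozen=True)
class EffortSummary:
    power_total: float      # J/min
    power_elastic: float
    power_resistive: float
    ptpmus: float           # cmH2O*s/min


def predicted_vc(sex: str, age: float, height: float,
                 reference_equation_id: str = "default") -> float:
    """Predicted vital capacity (l) for sex, age (years) and height (m)."""
    if not 18 <= age <= 110:
        raise ParameterError("age outside supported range 18-110")
    if not 1.2 <= height <= 2.2:
        raise ParameterError("height outside supported range 1.2-2.2 m")
    try:
        eq = VC_EQUATIONS[reference_equation_id][sex]
    except KeyError as exc:
        raise ParameterError(f"unknown equation/sex: {exc}") from exc
    return float(eq(height, age))


def chest_wall_elastance(vc_predicted: float, delta_pes: Optional[float] = None,
                         mode: str = "compliance_4pct_vc") -> float:
    """Chest-wall elastance (cmH2O/l) from predicted vital capacity.

    Default: chest-wall compliance is 4% of predicted VC per cmH2O, so
    ``Ecw = 1/(0.04*VC)``.  The alternative ``mode="pes_over_4pct_vc"``
    divides a measured per-breath Pes excursion by 4% VC instead.
    """
    if vc_predicted <= 0:
        raise ParameterError("vc_predicted must be > 0")
    if mode == "compliance_4pct_vc":
        return 1.0 / (0.04 * vc_predicted)
    if mode == "pes_over_4pct_vc":
        if delta_pes is None:
            raise ParameterError("delta_pes required for this mode")
        return float(delta_pes) / (0.04 * vc_predicted)
    raise ParameterError(f"unknown mode {mode!r}")


def chest_wall_for_patient(sex: str, age: float, height: float,
                           reference_equation_id: str = "default") -> ChestWall:
    vc = predicted_vc(sex, age, height, reference_equation_id)
    return ChestWall(ecw=chest_wall_elastance(vc), vc_predicted=vc,
                     reference_equation_id=reference_equation_id)


def _window_volume(record: WaveformRecord, breath: Breath) -> np.ndarray:
    """Volume over [effort onset, end inspiration], zero at effort onset."""
    fs = record.sampling_rate
    seg = record.flow[breath.effort_onset_idx:breath.end_insp_idx + 1]
    v = np.concatenate([[0.0], np.cumsum((seg[1:] + seg[:-1]) / 2.0) / fs])
    return v


def pmus_waveform(record: WaveformRecord, breath: Breath,
                  ecw: float) -> np.ndarray:
    """Muscular pressure over [effort onset, end inspiration] (cmH2O).

    ``Pmus(t) = Pes(effort onset) + Ecw*V(t) - Pes(t)``: the distance
    between the chest-wall recoil line anchored at effort onset and the
    measured Pes, with V integrated from flow (0 at effort onset).
    """
    if record.pes is None:
        raise AnalysisError("Pes channel required for Pmus")
    v = _window_volume(record, breath)
    pes = record.pes[breath.effort_onset_idx:breath.end_insp_idx + 1]
    return pes[0] + ecw * v - pes


def campbell_decomposition(record: WaveformRecord, breath: Breath,
                           ecw: float) -> EffortBreath:
    """Campbell-diagram WOB decomposition over one breath.

    Total WOB integrates Pmus over volume from effort onset to the end of
    inspiratory flow (the pre-flow intrinsic-PEEP segment is inside the
    window; it sweeps no volume but raises Pmus at flow onset, so the
    PEEPi burden is counted).  The elastic part is the area between the
    recoil line and the dynamic chord joining the two zero-flow points;
    the resistive part is the remainder.  Joules, via 0.0980665 J per
    cmH2O*l.  PTP is the Pmus-time integral over the window (cmH2O*s).
    """
    if breath.vt <= 0:
        raise AnalysisError("non-positive tidal volume")
    fs = record.sampling_rate
    pmus = pmus_waveform(record, breath, ecw)
    v = _window_volume(record, breath)
    pes = record.pes[breath.effort_onset_idx:breath.end_insp_idx + 1]

    total = float(np.trapezoid(pmus, v))          # cmH2O*l
    ptp = float(np.trapezoid(pmus, dx=1.0 / fs))  # cmH2O*s

    i_fo = breath.flow_onset_idx - breath.effort_onset_idx
    v0, vt = v[i_fo], v[-1]
    pes_a, pes_b = pes[i_fo], pes[-1]
    # recoil line evaluated at the chord's two volumes
    st0 = pes[0] + ecw * v0
    st1 = pes[0] + ecw * vt
    elastic = float((vt - v0) * ((st0 + st1) / 2.0 - (pes_a + pes_b) / 2.0))

    clamped = False
    if total < 0:
        warnings.warn("negative per-breath WOB floored at 0")
        total, elastic, resistive, clamped = 0.0, 0.0, 0.0, True
    else:
        resistive = total - elastic

    return EffortBreath(
        pmus=pmus, wob_total=total * J_PER_CMH2O_L,
        wob_elastic=elastic * J_PER_CMH2O_L,
        wob_resistive=resistive * J_PER_CMH2O_L,
        ptp=ptp, clamped=clamped)


def effort_summary(effort_breaths: Sequence[EffortBreath],
                   rr: float) -> EffortSummary:
    """Per-record powers: per-breath medians x respiratory rate.

    The total power is the sum of the elastic and resistive powers, as the
    per-breath totals are the sums of their components.
    """
    if not effort_breaths:
        raise AnalysisError("no effort breaths")
    pe = float(np.median([b.wob_elastic for b in effort_breaths])) * rr
    pr = float(np.median([b.wob_resistive for b in effort_breaths])) * rr
    ptp = float(np.median([b.ptp for b in effort_breaths])) * rr
    return EffortSummary(power_total=pe + pr, power_elastic=pe,
                         power_resistive=pr, ptpmus=ptp)
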