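"""Synthetic lung-ventilator simulator with known ground truth.

Generates spontaneous-breathing waveform records (flow, airway pressure,
esophageal pressure at 200 Hz) under pressure support (PS), automatic tube
compensation (ATC) or baseline settings, end-expiratory occlusion
maneuvers for P0.1, EIT pixel-map series with a controllable
ventro-dorsal gradient, and full randomized two-period crossover cohorts.

Physics: single-compartment equation of motion

    Paw + Pmus = Ers*V + Rphys*V' + PEEP_set + dP_ETT(V')

integrated at 2 kHz (explicit first-order stepping) and decimated to the
200 Hz recording rate after a boxcar anti-alias average.  Airway pressure
is taken machine-side of the endotracheal tube, so the tube drop separates
Paw from tracheal pressure.  Esophageal pressure follows the chest-wall
identity ``Pes = Pes0 + Ecw*V - Pmus`` (plus configurable noise and cardiac
artifact), which the effort-analysis chain inverts.

Intrinsic PEEP is produced by expiratory gas trapping (see ``_engine``),
so the patient must spend Pmus = PEEPi before inspiratory flow starts and
the end-expiratory alveolar pressure equals PEEP + PEEPi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from . import _engine
from .errors import ConfigurationError, ParameterError
from .ett import TubeSpec, default_tube
from .waveforms import WaveformRecord

__all__ = [
    "PatientParams",
    "VentilatorSettings",
    "SimConfig",
    "GroundTruth",
    "pmus_profile",
    "simulate_record",
    "simulate_eit_series",
    "simulate_cohort",
    "draw_patient",
    "ps_settings",
    "atc_settings",
]

#: Joules per cmH2O*l.
J_PER_CMH2O_L = 0.0980665

_INTERNAL_RATE = 2000.0
_OUTPUT_RATE = 200.0
_DECIM = 10
_MIN_TI = 0.15
_MAX_TI = 3.0
_TRIGGER_REFRACTORY = 0.30


@dataclass(frozen=True)
class PatientParams:
    """Respiratory mechanics, effort profile and demographics of one patient.

    Units: elastances cmH2O/l, resistance cmH2O/(l/s), pressures cmH2O,
    neural_ti s, neural_rr breaths/min, height m, ETT internal diameter mm,
    ETT length cm.
    """

    lung_elastance: float = 18.0
    chest_wall_elastance: float = 6.0
    physiological_resistance: float = 8.0
    intrinsic_peep: float = 1.0
    pmus_amplitude: float = 10.0
    neural_ti: float = 0.9
    neural_rr: float = 25.0
    sex: str = "male"
    age: float = 63.0
    height: float = 1.72
    ett_id: float = 7.5
    ett_length: float = 29.0

    def __post_init__(self) -> None:
        for name in ("lung_elastance", "chest_wall_elastance",
                     "physiological_resistance", "neural_ti", "neural_rr",
                     "height"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.intrinsic_peep < 0 or self.pmus_amplitude < 0:
            raise ParameterError(
                "intrinsic_peep and pmus_amplitude must be >= 0")
        if not 6.5 <= self.ett_id <= 9.0:
            raise ParameterError("ett_id must be within 6.5-9.0 mm")
        if self.neural_ti >= 60.0 / self.neural_rr:
            raise ParameterError("neural_ti must be shorter than the neural cycle")
        if self.sex not in ("male", "female"):
            raise ParameterError("sex must be 'male' or 'female'")

    @property
    def total_elastance(self) -> float:
        return self.lung_elastance + self.chest_wall_elastance

    def tube(self, model: str = "blasius") -> TubeSpec:
        return default_tube(self.ett_id, self.ett_length, model=model)


@dataclass(frozen=True)
class VentilatorSettings:
    """Ventilator mode and controller parameters.

    ``trigger_resistance`` models the demand-valve circuit: while the
    inspiratory valve is still closed the patient draws from the circuit
    and Paw dips below PEEP by ``trigger_resistance * flow``.
    """

    mode: str = "PS"
    peep_set: float = 4.0
    ps_level: float = 7.0
    atc_fraction: float = 0.0
    trigger_flow: float = 0.033
    rise_time_constant: float = 0.05
    cycle_off_fraction: float = 0.25
    valve_delay: float = 0.10
    trigger_resistance: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in ("PS", "ATC", "BASELINE"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.cycle_off_fraction < 1.0:
            raise ParameterError("cycle_off_fraction must be in (0, 1)")
        if not 0.0 <= self.atc_fraction <= 1.0:
            raise ParameterError("atc_fraction must be in [0, 1]")
        if self.mode == "PS" and self.atc_fraction != 0.0:
            raise ParameterError("atc_fraction must be 0 in PS mode")
        if self.mode == "ATC" and self.ps_level != 0.0:
            raise ParameterError("ps_level must be 0 in ATC mode")
        if min(self.peep_set, self.ps_level, self.trigger_flow,
               self.rise_time_constant, self.valve_delay,
               self.trigger_resistance) < 0:
            raise ParameterError("ventilator parameters must be >= 0")


def ps_settings(peep: float = 4.0, ps: float = 7.0, **kw) -> VentilatorSettings:
    """Low-pressure-support arm settings (ATC off)."""
    return VentilatorSettings(mode="PS", peep_set=peep, ps_level=ps,
                              atc_fraction=0.0, **kw)


def atc_settings(peep: float = 4.0, fraction: float = 1.0, **kw) -> VentilatorSettings:
    """Tube-compensation arm settings (PS 0, inspiratory compensation only)."""
    return VentilatorSettings(mode="ATC", peep_set=peep, ps_level=0.0,
                              atc_fraction=fraction, **kw)


@dataclass(frozen=True)
class SimConfig:
    """Recording / noise configuration for one simulated record."""

    sampling_rate: float = 200.0
    duration: float = 150.0
    seed: int = 0
    pes_noise_sd: float = 0.2
    cardiac_artifact_amplitude: float = 0.5
    cardiac_frequency: float = 1.2
    n_occlusions: int = 5
    occlusion_duration: float = 0.30
    pes_baseline: float = 8.0

    def __post_init__(self) -> None:
        if self.sampling_rate < 200.0:
            raise ParameterError("sampling_rate must be >= 200 Hz")
        if self.duration <= 2.0:
            raise ParameterError("duration too short")
        if self.n_occlusions < 0 or self.pes_noise_sd < 0:
            raise ParameterError("invalid config")


@dataclass
class GroundTruth:
    """Generator-side truth emitted alongside a simulated record.

    All per-sample arrays are on the same 200 Hz grid as the record and
    went through the identical anti-alias decimation, so linear identities
    (chest wall, occlusion contract) hold sample-wise.
    """

    time: np.ndarray
    pmus: np.ndarray
    volume: np.ndarray
    pes0: float
    ecw: float
    peep_total: float
    neural_period: float
    breath_onset_times: np.ndarray     # neural effort onsets of triggered breaths
    valve_open_times: np.ndarray
    cycle_off_times: np.ndarray
    wob_per_breath: np.ndarray         # J, integrated at 2 kHz in the engine
    occluded_cycles: set
    occlusion_onsets: np.ndarray       # 200 Hz sample indices
    occlusion_nsamples: int
    occlusion_p01: np.ndarray          # cmH2O, Pmus rise over first 100 ms


def pmus_profile(t_in_cycle, params: PatientParams):
    """Respiratory-muscle pressure profile within one neural cycle (cmH2O).

    Parabolic rise to ``pmus_amplitude`` over ``neural_ti`` followed by an
    exponential relaxation with time constant ``neural_ti/4``: continuous,
    non-negative, zero at onset.
    """
    if params.pmus_amplitude < 0:
        raise ParameterError("pmus_amplitude must be >= 0")
    t = np.asarray(t_in_cycle, dtype=float)
    ti = params.neural_ti
    amp = params.pmus_amplitude
    rising = t < ti
    out = np.where(
        rising,
        amp * (1.0 - (1.0 - np.minimum(t, ti) / ti) ** 2),
        amp * np.exp(-(np.maximum(t, ti) - ti) / (ti / 4.0)),
    )
    out = np.where(t < 0, 0.0, out)
    if np.isscalar(t_in_cycle) or out.ndim == 0:
        return float(out)
    return out


def _decimate(x: np.ndarray, n_out: int) -> np.ndarray:
    """Boxcar anti-alias average over each block of 10 samples, then keep one."""
    return x[: n_out * _DECIM].reshape(n_out, _DECIM).mean(axis=1)


def _schedule_occlusions(config: SimConfig, period: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Pick neural cycles whose effort onset will be occluded.

    Uniform random choice over eligible cycles in the final two minutes of
    the record (whole record when shorter), keeping at least one free cycle
    between occlusions.
    """
    if config.n_occlusions == 0:
        return np.empty(0, dtype=np.int64)
    t_lo = max(5.0, config.duration - 120.0)
    t_hi = config.duration - max(2.0, period)
    cycles = np.arange(int(np.ceil(t_lo / period)), int(t_hi / period))
    if cycles.size < 2 * config.n_occlusions:
        raise ConfigurationError(
            f"cannot place {config.n_occlusions} occlusions in {config.duration}s")
    chosen: list[int] = []
    pool = list(cycles)
    while len(chosen) < config.n_occlusions:
        if not pool:
            raise ConfigurationError("occlusion scheduling failed: cycles exhausted")
        c = int(pool[rng.integers(len(pool))])
        chosen.append(c)
        pool = [p for p in pool if abs(p - c) > 1]
    chosen.sort()
    # snap each onset to the 200 Hz grid, then to the 2 kHz grid
    idx200 = np.round(np.array(chosen) * period * _OUTPUT_RATE).astype(np.int64)
    return idx200 * _DECIM


def simulate_record(patient: PatientParams, settings: VentilatorSettings,
                    config: SimConfig) -> tuple[WaveformRecord, GroundTruth]:
    """Simulate one spontaneous-breathing record plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    period = 60.0 / patient.neural_rr
    n200 = int(round(config.duration * _OUTPUT_RATE))
    n2k = n200 * _DECIM
    dt = 1.0 / _INTERNAL_RATE

    t2k = np.arange(n2k) * dt
    pmus2k = pmus_profile(np.mod(t2k, period), patient)

    tube = patient.tube()
    k1, k2, kb = tube.coefficients()
    ers = patient.total_elastance
    v_trap = patient.intrinsic_peep / ers

    occ2k = _schedule_occlusions(config, period, rng)
    occ_nsamp2k = int(round(config.occlusion_duration * _INTERNAL_RATE))

    flow2k = np.empty(n2k)
    paw2k = np.empty(n2k)
    vol2k = np.empty(n2k)
    state2k = np.empty(n2k, dtype=np.int8)
    n_cycles = int(config.duration / period) + 2
    max_b = n_cycles + 8
    valve_open = np.full(max_b, -1, dtype=np.int64)
    cycle_off = np.full(max_b, -1, dtype=np.int64)
    breath_cycle = np.full(max_b, -1, dtype=np.int64)
    wob_cycle = np.zeros(n_cycles + 2)

    mode_atc = settings.mode == "ATC"
    nb = _engine.run_engine(
        n2k, dt, pmus2k, ers, patient.physiological_resistance, v_trap,
        settings.peep_set, mode_atc, settings.ps_level, settings.atc_fraction,
        k1, k2, kb, settings.trigger_flow, settings.valve_delay,
        max(settings.rise_time_constant, 1e-4), 0.05,
        settings.cycle_off_fraction, _MIN_TI, _MAX_TI,
        settings.trigger_resistance, _TRIGGER_REFRACTORY, period,
        occ2k, occ_nsamp2k,
        flow2k, paw2k, vol2k, state2k,
        valve_open, cycle_off, breath_cycle, wob_cycle)
    nb = min(nb, max_b)
    if not np.all(np.isfinite(vol2k)):
        raise ConfigurationError("integration diverged; check parameters")

    flow = _decimate(flow2k, n200)
    paw = _decimate(paw2k, n200)
    vol = _decimate(vol2k, n200)
    pmus = _decimate(pmus2k, n200)
    time = np.arange(n200) / _OUTPUT_RATE

    pes = config.pes_baseline + patient.chest_wall_elastance * vol - pmus
    if config.cardiac_artifact_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        pes = pes + config.cardiac_artifact_amplitude * np.sin(
            2 * np.pi * config.cardiac_frequency * time + phase)
    if config.pes_noise_sd > 0:
        pes = pes + rng.normal(0.0, config.pes_noise_sd, n200)

    record = WaveformRecord(
        time=time, flow=flow, paw=paw, pes=pes, sampling_rate=_OUTPUT_RATE,
        meta={"mode": settings.mode, "seed": config.seed,
              "peep_set": settings.peep_set, "ett_id": patient.ett_id})

    complete = cycle_off[:nb] >= 0
    vo = valve_open[:nb][complete]
    co = cycle_off[:nb][complete]
    bc = breath_cycle[:nb][complete]
    occ200 = (occ2k // _DECIM).astype(np.int64)
    occ_n200 = occ_nsamp2k // _DECIM
    p01_true = np.array([
        pmus[j + 20] - pmus[j] if j + 20 < n200 else np.nan for j in occ200])
    occluded_cycles = {int((j / _OUTPUT_RATE) // period) for j in occ200}

    gt = GroundTruth(
        time=time, pmus=pmus, volume=vol, pes0=config.pes_baseline,
        ecw=patient.chest_wall_elastance,
        peep_total=settings.peep_set + patient.intrinsic_peep,
        neural_period=period,
        breath_onset_times=bc * period,
        valve_open_times=vo * dt,
        cycle_off_times=co * dt,
        wob_per_breath=wob_cycle[bc] * J_PER_CMH2O_L,
        occluded_cycles=occluded_cycles,
        occlusion_onsets=occ200,
        occlusion_nsamples=occ_n200,
        occlusion_p01=p01_true)
    return record, gt


# ---------------------------------------------------------------------------
# EIT generator
# ---------------------------------------------------------------------------

def _lung_amplitude_map(gradient: float, base: float = 1.0,
                        grid: int = 32) -> np.ndarray:
    """Two elliptical lung regions; amplitude scaled ventro-dorsally.

    Row 0 is the most ventral row.  Per-pixel tidal amplitude is
    ``base * (1 + gradient*(2r - 1))`` with r = row/(grid-1), inside the
    ellipses and zero outside.  The ellipses are symmetric about the grid
    mid-plane so a zero gradient yields a perfectly symmetric map.
    """
    rows, cols = np.mgrid[0:grid, 0:grid].astype(float)
    c0 = (grid - 1) / 2.0
    left = ((rows - c0) / 10.0) ** 2 + ((cols - 9.0) / 5.5) ** 2 <= 1.0
    right = ((rows - c0) / 10.0) ** 2 + ((cols - 22.0) / 5.5) ** 2 <= 1.0
    mask = left | right
    r = rows / (grid - 1.0)
    amp = base * (1.0 + gradient * (2.0 * r - 1.0))
    return np.where(mask, amp, 0.0)


def simulate_eit_series(patient: PatientParams, gradient: float,
                        config: SimConfig, noise_sd: float = 0.0):
    """Synthetic 32x32 EIT frame series at 20 Hz tracking tidal volume.

    ``gradient`` in [-1, +1] shifts tidal amplitude from all-ventral (-1)
    to all-dorsal (+1).  Pixel time courses follow a raised-cosine breath
    of the patient's neural rate; the generated amplitude map and the
    breath boundary times are attached as ground truth.
    """
    from .eit import EitFrameSeries  # local import: eit is analysis-side

    if not -1.0 <= gradient <= 1.0:
        raise ParameterError("gradient must be within [-1, 1]")
    rng = np.random.default_rng(config.seed + 104729)
    frame_rate = 20.0
    n = int(round(config.duration * frame_rate))
    times = np.arange(n) / frame_rate
    period = 60.0 / patient.neural_rr
    v = 0.5 * (1.0 - np.cos(2.0 * np.pi * times / period))
    amp = _lung_amplitude_map(gradient)
    frames = 100.0 + amp[None, :, :] * v[:, None, None]
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)
    k_max = int(times[-1] / period)
    intervals = [(k * period, k * period + period / 2.0) for k in range(k_max)]
    return EitFrameSeries(frames=frames, frame_rate=frame_rate, times=times,
                          amplitude_map=amp, breath_intervals=intervals)


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

def draw_patient(rng: np.random.Generator) -> PatientParams:
    """Draw one patient from the documented cohort distributions.

    Demographics follow the studied population (ICU adults ready to wean,
    ~3:1 male); chest-wall elastance is derived from the patient's
    predicted vital capacity so the generative chest wall matches the one
    the analysis chain reconstructs; total elastance is log-normal around
    25 cmH2O/l, airway resistance log-normal around 8 cmH2O/(l/s),
    intrinsic PEEP log-normal around 1 cmH2O, effort amplitude 8-12 cmH2O
    and neural rate 22-30 breaths/min.
    """
    from .effort import chest_wall_elastance, predicted_vc

    sex = "male" if rng.random() < 0.75 else "female"
    age = float(np.clip(rng.normal(63.0, 12.0), 25.0, 88.0))
    height = float(np.clip(
        rng.normal(1.75 if sex == "male" else 1.62, 0.06), 1.45, 1.98))
    ett_id = float(rng.choice([7.0, 7.5, 8.0, 8.5],
                              p=[0.2, 0.35, 0.3, 0.15]))
    ecw = chest_wall_elastance(predicted_vc(sex, age, height))
    ers = float(np.clip(rng.lognormal(np.log(25.0), 0.25), 12.0, 50.0))
    el = max(ers - ecw, 5.0)
    rphys = float(np.clip(rng.lognormal(np.log(8.0), 0.30), 3.0, 20.0))
    peepi = float(np.clip(rng.lognormal(np.log(1.0), 0.5), 0.1, 4.0))
    rr = float(rng.uniform(22.0, 30.0))
    ti = float(np.clip(rng.normal(0.9, 0.08), 0.6, 0.45 * 60.0 / rr))
    amp = float(rng.uniform(8.0, 12.0))
    return PatientParams(
        lung_elastance=el, chest_wall_elastance=ecw,
        physiological_resistance=rphys, intrinsic_peep=peepi,
        pmus_amplitude=amp, neural_ti=ti, neural_rr=rr,
        sex=sex, age=age, height=height, ett_id=ett_id)


_DEFAULT_EFFECT = {"ps": 1.0, "atc": 1.35}


def simulate_cohort(n_patients: int = 20, effect: Optional[dict] = None,
                    seed: int = 0, config: Optional[SimConfig] = None,
                    include_eit: bool = True, return_records: bool = False,
                    window: float = 120.0):
    """Simulate and analyse a full randomized crossover cohort.

    Each patient receives both arms (PS 7/PEEP 4 and ATC 100%/PEEP 4) in a
    random sequence; ``effect`` maps arm name to a respiratory-drive
    multiplier applied to the patient's effort amplitude (default ATC 1.35,
    the calibrated drive increase when tube compensation withdraws the
    extra support).  Outcomes are *measured* by the package's own analysis
    chain on each simulated record, not copied from ground truth.

    Returns ``(dataset, records)`` where ``dataset`` is a
    :class:`weanlab.stats.CrossoverDataset` and ``records`` maps
    ``(patient_id, arm)`` to ``(record, ground_truth)`` when
    ``return_records`` is true (else an empty dict).
    """
    import pandas as pd

    from .pipeline import analyze_record
    from .stats import CrossoverDataset

    if n_patients < 2:
        raise ParameterError("n_patients must be >= 2")
    if n_patients % 2:
        warnings.warn("odd cohort size: extra patient's sequence drawn at random")
    effect = {**_DEFAULT_EFFECT, **(effect or {})}
    config = config or SimConfig()
    rng = np.random.default_rng(seed)

    sequences = ["ATC_first"] * (n_patients // 2) + ["PS_first"] * (n_patients // 2)
    if n_patients % 2:
        sequences.append("ATC_first" if rng.random() < 0.5 else "PS_first")
    rng.shuffle(sequences)

    rows = []
    records: dict = {}
    for pid in range(1, n_patients + 1):
        patient = draw_patient(rng)
        gradient = float(np.clip(rng.normal(0.05, 0.10), -0.5, 0.8))
        row = {"patient": pid, "sequence": sequences[pid - 1]}
        for arm, settings in (("atc", atc_settings(peep=4.0, fraction=1.0)),
                              ("ps", ps_settings(peep=4.0, ps=7.0))):
            p_arm = replace(patient,
                            pmus_amplitude=patient.pmus_amplitude * effect[arm])
            cfg = replace(config, seed=int(rng.integers(2**31 - 1)))
            rec, gt = simulate_record(p_arm, settings, cfg)
            metrics = analyze_record(rec, patient=p_arm, window=window)
            for name, value in metrics.items():
                row[f"y_{name}_{arm}"] = value
            if include_eit:
                from .eit import eit_indexes, tidal_image
                eit_cfg = replace(cfg, duration=min(config.duration, 60.0))
                series = simulate_eit_series(p_arm, gradient, eit_cfg,
                                             noise_sd=0.005)
                img = tidal_image(series, series.breath_intervals)
                idx = eit_indexes(img)
                row[f"y_ap_ratio_{arm}"] = idx.ap_ratio
                row[f"y_center_of_ventilation_{arm}"] = idx.center_of_ventilation
                row[f"y_gi_index_{arm}"] = idx.gi_index
                row[f"y_variation_coefficient_{arm}"] = idx.variation_coefficient
            if return_records:
                records[(pid, arm)] = (rec, gt)
        rows.append(row)

    table = pd.DataFrame(rows)
    return CrossoverDataset(table=table), records
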