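"""End-to-end analysis pipeline and reporting.

``analyze_record`` runs the full per-record chain (occlusion detection,
breath segmentation, breathing pattern, ventilator metrics, intrinsic
PEEP, P0.1, Campbell effort decomposition, tube excess-support index) on
the final analysis window of a waveform record.  ``run_pipeline`` drives
a whole study from a config mapping: either a simulated crossover cohort
or a list of recorded files, producing per-record metric tables,
arm-level median (IQR) summaries, the crossover tests for each outcome,
and a provenance block (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .effort import (campbell_decomposition, chest_wall_for_patient,
                     effort_summary)
from .errors import AnalysisError, ConfigurationError
from .ett import TubeSpec, default_tube, excess_support_percent
from .waveforms import (WaveformRecord, breathing_pattern, detect_occlusions,
                        intrinsic_peep, p01, segment_breaths,
                        ventilator_pressures)

log = logging.getLogger("weanlab")

__all__ = ["AnalysisReport", "analyze_record", "run_pipeline"]

_METRIC_KEYS = [
    "vt", "rr", "minute_ventilation", "ti", "te", "ti_te_ratio", "rr_over_vt",
    "peep", "dp_trig", "dt_trig", "max_insp_pressure", "max_insp_flow",
    "peepi", "p01", "wob_total", "power_total", "power_elastic",
    "power_resistive", "ptpmus", "excess_support",
]


@dataclass
class AnalysisReport:
    per_record: pd.DataFrame
    summary: Optional[pd.DataFrame]
    tests: dict
    provenance: dict
    errors: list = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "per_record": self.per_record.to_dict(orient="records"),
            "summary": (None if self.summary is None
                        else self.summary.to_dict(orient="records")),
            "tests": self.tests,
            "errors": self.errors,
        }
        return json.dumps(payload, indent=1, sort_keys=True, default=str)


def analyze_record(record: WaveformRecord, patient=None, ecw: float = None,
                   tube: Optional[TubeSpec] = None,
                   window: float = 120.0) -> dict:
    """All per-record metrics over the final ``window`` seconds.

    ``patient`` (anything exposing sex/age/height and ett_id) supplies the
    chest wall and tube when ``ecw``/``tube`` are not given explicitly.
    Returns a flat dict (NaN where a quantity could not be measured; P0.1
    is NaN when no occlusion is present).
    """
    if window and record.duration > window:
        record = record.slice(record.time[-1] - window, record.time[-1])
    out = {k: np.nan for k in _METRIC_KEYS}

    occlusions = detect_occlusions(record)
    breaths = segment_breaths(record, occlusions=occlusions)
    log.debug("analyze_record: %d breaths, %d occlusions",
              len(breaths), len(occlusions))
    if not breaths:
        return out

    pattern = breathing_pattern(breaths, record)
    for k in ("vt", "rr", "minute_ventilation", "ti", "te", "ti_te_ratio",
              "rr_over_vt"):
        out[k] = getattr(pattern, k)
    vm = ventilator_pressures(record, breaths, occlusions=occlusions)
    out["peep"] = vm.peep_measured
    out["dp_trig"] = vm.dp_trig
    out["dt_trig"] = vm.dt_trig
    out["max_insp_pressure"] = vm.max_insp_pressure
    out["max_insp_flow"] = vm.max_insp_flow
    out["peepi"] = float(np.median([intrinsic_peep(record, b)
                                    for b in breaths]))
    drive = p01(record, occlusions)
    out["p01"] = np.nan if drive is None else drive

    if ecw is None and patient is not None:
        if hasattr(patient, "chest_wall_elastance"):
            ecw = patient.chest_wall_elastance
        else:
            ecw = chest_wall_for_patient(patient.sex, patient.age,
                                         patient.height).ecw
    if ecw is not None and record.pes is not None:
        eb = []
        for b in breaths:
            try:
                eb.append(campbell_decomposition(record, b, ecw))
            except AnalysisError:
                log.debug("breath rejected in effort analysis")
        if eb:
            summ = effort_summary(eb, pattern.rr)
            out["wob_total"] = float(np.median([e.wob_total for e in eb]))
            out["power_total"] = summ.power_total
            out["power_elastic"] = summ.power_elastic
            out["power_resistive"] = summ.power_resistive
            out["ptpmus"] = summ.ptpmus

    if tube is None:
        ett_id = getattr(patient, "ett_id", None) or record.meta.get("ett_id")
        if ett_id:
            tube = default_tube(float(ett_id))
    if tube is not None:
        excess = excess_support_percent(record, vm.peep_measured, tube,
                                        breaths=breaths)
        out["excess_support"] = np.nan if excess is None else excess
    return out


def _config_hash(config: dict) -> str:
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _summarise(dataset, tests_for: tuple = ("power_total",)) -> tuple:
    from .stats import crossover_tests, median_iqr, wilcoxon_signed_rank

    rows, tests = [], {}
    for name in dataset.outcomes:
        y_atc, y_ps = dataset.paired(name)
        if y_atc.size < 2:
            continue
        m_a, q1_a, q3_a = median_iqr(y_atc)
        m_p, q1_p, q3_p = median_iqr(y_ps)
        res = wilcoxon_signed_rank(y_atc, y_ps)
        rows.append({"outcome": name,
                     "atc": f"{m_a:.3g} ({q1_a:.3g}-{q3_a:.3g})",
                     "ps": f"{m_p:.3g} ({q1_p:.3g}-{q3_p:.3g})",
                     "p_value": res.p_value, "n": res.n})
        if name in tests_for:
            co = crossover_tests(dataset, name)
            tests[name] = {
                k: (v if isinstance(v, str)
                    else {"statistic": v.statistic, "p_value": v.p_value,
                          "method": v.method, "n": v.n})
                for k, v in co.items()}
    return pd.DataFrame(rows), tests


def run_pipeline(config: Union[dict, str, Path]) -> AnalysisReport:
    """Run the study pipeline described by ``config`` (mapping or YAML path).

    Simulation mode (``simulate:`` block): generates and analyses a
    crossover cohort.  File mode (``records:`` list of
    ``{patient, arm, path, ...}``): ingests and analyses recordings,
    pairing arms per patient.  Writes the report under ``output_dir`` when
    set.  Failures of individual stages are collected into
    ``report.errors`` rather than aborting the whole run.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    seed = int(config.get("seed", 0))
    window = float(config.get("window_s", 120.0))
    errors: list[str] = []
    dataset = None

    if "simulate" in config:
        from .simulate import SimConfig, simulate_cohort

        sim = dict(config["simulate"])
        sim_cfg = SimConfig(duration=float(sim.get("duration_s", 150.0)),
                            seed=seed)
        dataset, _ = simulate_cohort(
            n_patients=int(sim.get("n_patients", 20)),
            effect=sim.get("effect"), seed=seed, config=sim_cfg,
            include_eit=bool(sim.get("include_eit",
                                     config.get("eit", {}).get("enabled", True))),
            window=window)
        table = dataset.table
        per_record = table
    elif "records" in config:
        from .io import read_waveforms
        from .stats import CrossoverDataset

        rows = []
        for entry in config["records"]:
            try:
                rec = read_waveforms(entry["path"])
                metrics = analyze_record(rec, patient=None,
                                         ecw=entry.get("ecw"),
                                         tube=(default_tube(entry["ett_id"])
                                               if "ett_id" in entry else None),
                                         window=window)
                rows.append({"patient": entry.get("patient"),
                             "arm": entry.get("arm"), **metrics})
            except Exception as exc:  # collected, reported, non-zero exit
                errors.append(f"{entry.get('path')}: {exc}")
        per_record = pd.DataFrame(rows)
        if {"patient", "arm"}.issubset(per_record.columns):
            try:
                wide = per_record.pivot(index="patient", columns="arm")
                wide.columns = [f"y_{m}_{a}" for m, a in wide.columns]
                wide = wide.reset_index()
                wide["sequence"] = "unknown"
                if any(c.endswith("_atc") for c in wide.columns):
                    dataset = CrossoverDataset(table=wide)
            except Exception as exc:
                errors.append(f"pairing arms failed: {exc}")
    else:
        raise ConfigurationError("config needs a 'simulate' or 'records' block")

    summary, tests = (None, {})
    if dataset is not None:
        seqs = set(dataset.table["sequence"])
        tests_for = ("power_total",) if seqs != {"unknown"} else ()
        try:
            summary, tests = _summarise(dataset, tests_for)
        except Exception as exc:
            errors.append(f"summary failed: {exc}")

    report = AnalysisReport(
        per_record=per_record, summary=summary, tests=tests,
        provenance={"config_hash": _config_hash(config), "seed": seed,
                    "version": __version__, "window_s": window},
        errors=errors)

    out_dir = config.get("output_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_record.to_csv(out / "per_record.csv", index=False)
        if summary is not None:
            summary.to_csv(out / "summary.csv", index=False)
        (out / "report.json").write_text(report.to_json())
    return report
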