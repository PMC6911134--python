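"""Delimited-text ingestion and serialisation of waveform and EIT data.

Waveform files are plain CSV with the columns ``time_s``, ``flow_lps``,
``paw_cmh2o`` and (optionally) ``pes_cmh2o``, preceded by ``#``-prefixed
``key = value`` metadata lines (sampling_rate, mode, seed, ...).  Records
are validated on read and resampled to exactly 200 Hz by linear
interpolation when the file's rate differs.

EIT frame series are stored as one 32x32 comma-separated matrix per frame
with ``# frame <i>`` separators, plus a JSON sidecar carrying the frame
rate and grid size.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .eit import EitFrameSeries
from .errors import IngestionError
from .waveforms import TARGET_RATE, WaveformRecord

__all__ = ["read_waveforms", "write_waveforms", "read_eit", "write_eit"]

_CHANNELS = ("time_s", "flow_lps", "paw_cmh2o", "pes_cmh2o")


def write_waveforms(record: WaveformRecord, path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sampling_rate = {record.sampling_rate}\n")
        for key, value in sorted(record.meta.items()):
            fh.write(f"# {key} = {value}\n")
        cols = {"time_s": record.time, "flow_lps": record.flow,
                "paw_cmh2o": record.paw}
        if record.pes is not None:
            cols["pes_cmh2o"] = record.pes
        # %.17g: lossless text round-trip for float64
        pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.17g")


def _parse_meta(lines: list[str]) -> dict:
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if "=" not in body:
            continue
        key, _, value = body.partition("=")
        value = value.strip()
        try:
            parsed = json.loads(value)
        except json.JSONDecodeError:
            parsed = value
        meta[key.strip()] = parsed
    return meta


def read_waveforms(path: Union[str, Path],
                   metadata: Optional[dict] = None) -> WaveformRecord:
    """Read and validate a waveform CSV; resample to 200 Hz if needed.

    A missing Pes column is allowed (the record is flagged and effort
    analysis will refuse it); a missing flow or Paw column, or a
    non-monotone time axis, raises :class:`IngestionError` with the
    offending location.
    """
    path = Path(path)
    header_lines = []
    with path.open() as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                header_lines.append(line)
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, float_precision="round_trip")
    meta = _parse_meta(header_lines)
    if metadata:
        meta.update(metadata)

    for col in ("time_s", "flow_lps", "paw_cmh2o"):
        if col not in df.columns:
            raise IngestionError(f"{path.name}: missing channel {col!r}")
    time = df["time_s"].to_numpy(dtype=float)
    if time.size >= 2:
        dt = np.diff(time)
        if np.any(dt <= 0):
            line_no = int(np.argmax(dt <= 0)) + 2 + len(header_lines) + 1
            raise IngestionError(
                f"{path.name}: time not strictly increasing (line {line_no})")
    flow = df["flow_lps"].to_numpy(dtype=float)
    paw = df["paw_cmh2o"].to_numpy(dtype=float)
    pes = (df["pes_cmh2o"].to_numpy(dtype=float)
           if "pes_cmh2o" in df.columns else None)
    if pes is None:
        meta["effort_analysis"] = "unavailable: Pes channel absent"

    rate = meta.get("sampling_rate")
    if rate is None and time.size >= 2:
        rate = 1.0 / float(np.median(np.diff(time)))
    rate = float(rate)
    if abs(rate - TARGET_RATE) > 1e-6:
        new_time = np.arange(time[0], time[-1] + 0.5 / TARGET_RATE,
                             1.0 / TARGET_RATE)
        flow = np.interp(new_time, time, flow)
        paw = np.interp(new_time, time, paw)
        if pes is not None:
            pes = np.interp(new_time, time, pes)
        time = new_time
        meta["resampled_from_hz"] = rate
    meta["sampling_rate"] = TARGET_RATE
    return WaveformRecord(time=time, flow=flow, paw=paw, pes=pes,
                          sampling_rate=TARGET_RATE, meta=meta)


def write_eit(series: EitFrameSeries, path: Union[str, Path]) -> None:
    path = Path(path)
    n, rows, cols = series.frames.shape
    with path.open("w") as fh:
        for i in range(n):
            fh.write(f"# frame {i}\n")
            np.savetxt(fh, series.frames[i], fmt="%.6g", delimiter=",")
    sidecar = {"frame_rate": series.frame_rate, "n_frames": n,
               "grid": [rows, cols], "row_order": "ventral_first"}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_eit(path: Union[str, Path]) -> EitFrameSeries:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    rows, cols = sidecar["grid"]
    frames = []
    block: list[str] = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                if block:
                    frames.append(np.loadtxt(_io.StringIO("".join(block)),
                                             delimiter=","))
                    block = []
            else:
                block.append(line)
    if block:
        frames.append(np.loadtxt(_io.StringIO("".join(block)), delimiter=","))
    arr = np.asarray(frames)
    if arr.shape[1:] != (rows, cols):
        raise IngestionError(f"{path.name}: frame shape {arr.shape[1:]} "
                             f"does not match sidecar grid {(rows, cols)}")
    return EitFrameSeries(frames=arr, frame_rate=float(sidecar["frame_rate"]))
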