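"""Ventilation-distribution indexes from EIT pixel tidal-variation maps.

Frames are 32x32 reconstructed impedance images at 20 Hz, rows ordered
ventral (row 0) to dorsal (row 31).  The tidal image averages, over
breaths, the end-inspiratory minus end-expiratory pixel value.  Four
standard indexes summarise the distribution:

* anterior-to-posterior ratio: total tidal impedance in the ventral half
  of the image over the dorsal half;
* center of ventilation: tidal-impedance-weighted centroid along the
  ventro-dorsal axis, in % (0 = most ventral row centre, 100 = most
  dorsal);
* global inhomogeneity (GI) index: sum of absolute deviations of lung-ROI
  pixels from the ROI median, normalised by the ROI total;
* coefficient of variation: population SD over mean of lung-ROI pixels.

The lung ROI keeps pixels at or above a fraction (default 20%) of the
maximum tidal amplitude.  All indexes are invariant to a global rescaling
of the tidal image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import AnalysisError, ParameterError

__all__ = ["EitFrameSeries", "TidalImage", "EitIndexes",
           "tidal_image", "eit_indexes"]


@dataclass
class EitFrameSeries:
    """32x32 impedance frames over time (ventral rows first)."""

    frames: np.ndarray              # (n_frames, 32, 32)
    frame_rate: float               # Hz
    times: Optional[np.ndarray] = None
    amplitude_map: Optional[np.ndarray] = field(default=None, repr=False)
    breath_intervals: Optional[list] = None   # [(t_end_exp, t_end_insp)]

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ParameterError("frames must be (n, rows, cols)")
        if self.frame_rate <= 0:
            raise ParameterError("frame_rate must be > 0")
        if self.times is None:
            self.times = np.arange(self.frames.shape[0]) / self.frame_rate


@dataclass(frozen=True)
class TidalImage:
    """Per-pixel tidal amplitude (arbitrary units, >= 0)."""

    dz: np.ndarray
    n_breaths: int
    n_clamped: int = 0              # negative pixels clamped to 0
    orientation: str = "ventral_rows_first"


@dataclass(frozen=True)
class EitIndexes:
    ap_ratio: float
    center_of_ventilation: float    # %
    gi_index: float
    variation_coefficient: float


def tidal_image(series: EitFrameSeries,
                breath_intervals: Optional[Sequence[tuple]] = None) -> TidalImage:
    """Mean end-inspiratory minus end-expiratory image over breaths.

    ``breath_intervals`` is a sequence of ``(t_end_exp, t_end_insp)`` times
    in seconds; the series' own ground-truth intervals are used when
    omitted.  Negative pixel differences are clamped to 0 and counted.
    """
    if breath_intervals is None:
        breath_intervals = series.breath_intervals
    if not breath_intervals:
        raise AnalysisError("no complete breath in the series")
    n = series.frames.shape[0]
    acc = np.zeros(series.frames.shape[1:])
    used = 0
    for t_ee, t_ei in breath_intervals:
        i_ee = int(round(t_ee * series.frame_rate))
        i_ei = int(round(t_ei * series.frame_rate))
        if not (0 <= i_ee < n and 0 <= i_ei < n):
            continue
        acc += series.frames[i_ei] - series.frames[i_ee]
        used += 1
    if used == 0:
        raise AnalysisError("no breath interval falls inside the series")
    dz = acc / used
    n_clamped = int(np.sum(dz < 0))
    return TidalImage(dz=np.maximum(dz, 0.0), n_breaths=used,
                      n_clamped=n_clamped)


def eit_indexes(image: TidalImage, roi_threshold: float = 0.20) -> EitIndexes:
    """Ventilation-distribution indexes of a tidal image."""
    dz = image.dz
    total = dz.sum()
    if total <= 0:
        raise AnalysisError("all-zero tidal image")
    n_rows = dz.shape[0]
    half = n_rows // 2
    dorsal = dz[half:].sum()
    ap_ratio = float(dz[:half].sum() / dorsal) if dorsal > 0 else np.inf

    r = np.arange(n_rows) / (n_rows - 1.0)
    cov = float(100.0 * np.sum(r[:, None] * dz) / total)

    roi = dz >= roi_threshold * dz.max()
    vals = dz[roi]
    if vals.size == 0:
        raise AnalysisError("empty lung ROI")
    gi = float(np.sum(np.abs(vals - np.median(vals))) / vals.sum())
    varco = float(vals.std() / vals.mean())
    return EitIndexes(ap_ratio=ap_ratio, center_of_ventilation=cov,
                      gi_index=gi, variation_coefficient=varco)
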