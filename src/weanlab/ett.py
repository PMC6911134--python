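"""Endotracheal-tube (ETT) pressure-drop model and tube-compensation analysis.

The flow resistance of an adult endotracheal tube is strongly non-linear.
Two laws are supported:

* ``blasius`` (default): turbulent smooth-pipe law,
  ``dP = k * |Q|**1.75 * sign(Q)`` with ``k = C * L / d**4.75``
  (L tube length in cm, d internal diameter in mm).  The constant ``C`` is
  calibrated so that a 7.5 mm ID, 29 cm tube drops 6.5 cmH2O at 1 l/s,
  inside the 5-8 cmH2O range reported for adult tubes.
* ``rohrer``: ``dP = k1*Q + k2*Q*|Q|`` with user-supplied coefficients.
  Shipped defaults per ID are least-squares fits of the Blasius curve over
  0-1.5 l/s, so both laws agree closely in the clinical flow range.

The *ideal* compensating pressure is the airway pressure that would exactly
offset the tube drop during inspiration: ``PEEP + dP_ETT(flow)``.  The excess
support index compares the pressure the ventilator actually delivered above
PEEP with that ideal profile, summed over inspiratory samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = [
    "BLASIUS_EXPONENT",
    "TubeSpec",
    "default_tube",
    "rohrer_fit",
    "tube_pressure_drop",
    "ideal_pressure_profile",
    "excess_support_percent",
]

BLASIUS_EXPONENT = 1.75

#: Calibration constant: dP(1 l/s) = _BLASIUS_C * L_cm / d_mm**4.75.
#: Chosen so dP(1 l/s, ID 7.5 mm, L 29 cm) = 6.5 cmH2O.
_BLASIUS_C = 6.5 * 7.5**4.75 / 29.0

#: Default tube length (cm) when only the internal diameter is known.
DEFAULT_TUBE_LENGTH_CM = 29.0


def _blasius_k(internal_diameter: float, length: float) -> float:
    return _BLASIUS_C * length / internal_diameter**4.75


def rohrer_fit(internal_diameter: float, length: float = DEFAULT_TUBE_LENGTH_CM,
               qmax: float = 1.5) -> tuple[float, float]:
    """Least-squares Rohrer coefficients (k1, k2) matching the Blasius curve.

    Fit of ``k1*Q + k2*Q**2`` to ``k_b*Q**1.75`` on a dense grid over
    ``(0, qmax]`` l/s.  Deterministic, no randomness.
    """
    kb = _blasius_k(internal_diameter, length)
    q = np.linspace(0.01, qmax, 300)
    target = kb * q**BLASIUS_EXPONENT
    basis = np.column_stack([q, q**2])
    coef, *_ = np.linalg.lstsq(basis, target, rcond=None)
    k1, k2 = float(coef[0]), float(coef[1])
    return max(k1, 0.0), max(k2, 0.0)


@dataclass(frozen=True)
class TubeSpec:
    """Endotracheal tube geometry and pressure-flow law.

    Parameters
    ----------
    internal_diameter : float
        ID in mm.
    length : float
        Tube length in cm.
    model : str
        ``"blasius"`` or ``"rohrer"``.
    k1, k2 : float
        Rohrer coefficients, cmH2O/(l/s) and cmH2O/(l/s)^2.  Ignored by the
        Blasius model.
    k_blasius : float
        Blasius coefficient, cmH2O/(l/s)^1.75.  Derived from geometry when
        left at 0.  Ignored by the Rohrer model.
    """

    internal_diameter: float
    length: float = DEFAULT_TUBE_LENGTH_CM
    model: str = "blasius"
    k1: float = 0.0
    k2: float = 0.0
    k_blasius: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.internal_diameter <= 0 or self.length <= 0:
            raise ParameterError("tube diameter and length must be positive")
        if self.model not in ("blasius", "rohrer"):
            raise ParameterError(f"unknown tube model {self.model!r}")
        if min(self.k1, self.k2, self.k_blasius) < 0:
            raise ParameterError("tube coefficients must be >= 0")
        if self.model == "blasius" and self.k_blasius == 0.0:
            object.__setattr__(
                self, "k_blasius", _blasius_k(self.internal_diameter, self.length)
            )

    def coefficients(self) -> tuple[float, float, float]:
        """(k1, k2, k_blasius) with exactly the chosen model's terms non-zero."""
        if self.model == "blasius":
            return 0.0, 0.0, self.k_blasius
        return self.k1, self.k2, 0.0


def default_tube(internal_diameter: float, length: float = DEFAULT_TUBE_LENGTH_CM,
                 model: str = "blasius") -> TubeSpec:
    """Tube spec for a given ID using the shipped coefficient calibration."""
    if model not in ("blasius", "rohrer"):
        raise ParameterError(f"unknown tube model {model!r}")
    if model == "rohrer":
        k1, k2 = rohrer_fit(internal_diameter, length)
        return TubeSpec(internal_diameter, length, model="rohrer", k1=k1, k2=k2)
    return TubeSpec(internal_diameter, length, model="blasius")


def tube_pressure_drop(flow, tube: TubeSpec):
    """Pressure drop across the tube (cmH2O) at the given flow(s) in l/s.

    Odd in flow (machine side minus tracheal side is positive for
    inspiratory, i.e. positive, flow) and zero at zero flow.
    """
    q = np.asarray(flow, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ParameterError("flow must be finite")
    k1, k2, kb = tube.coefficients()
    aq = np.abs(q)
    dp = k1 * q + k2 * q * aq + kb * aq**(BLASIUS_EXPONENT - 1.0) * q
    if np.isscalar(flow) or dp.ndim == 0:
        return float(dp)
    return dp


def _inspiratory_mask(record, breaths=None) -> np.ndarray:
    """Boolean mask of inspiratory samples.

    With segmented breaths: union of [flow_onset, end_insp] windows
    restricted to positive flow.  Without: all positive-flow samples.
    """
    flow = record.flow
    if breaths is None:
        return flow > 0
    mask = np.zeros(flow.size, dtype=bool)
    for b in breaths:
        mask[b.flow_onset_idx:b.end_insp_idx + 1] = True
    return mask & (flow > 0)


def ideal_pressure_profile(record, peep: float, tube: TubeSpec, breaths=None) -> np.ndarray:
    """Ideal tube-compensating airway pressure trace.

    ``peep + dP_ETT(flow)`` on inspiratory samples, ``peep`` elsewhere.
    """
    mask = _inspiratory_mask(record, breaths)
    ideal = np.full(record.flow.size, float(peep))
    ideal[mask] += tube_pressure_drop(record.flow[mask], tube)
    return ideal


def excess_support_percent(record, peep: float, tube: TubeSpec, breaths=None):
    """Excess of delivered over ideal tube-compensating pressure, in percent.

    ``100 * (sum_insp(Paw - PEEP) - sum_insp(Pideal - PEEP)) / sum_insp(Pideal - PEEP)``

    Returns ``None`` when no inspiratory flow is present (the ideal sum is
    zero and the ratio undefined).
    """
    mask = _inspiratory_mask(record, breaths)
    if not mask.any():
        return None
    ideal_above = tube_pressure_drop(record.flow[mask], tube)
    denom = float(np.sum(ideal_above))
    if denom <= 0:
        return None
    delivered = float(np.sum(record.paw[mask] - peep))
    return 100.0 * (delivered - denom) / denom
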