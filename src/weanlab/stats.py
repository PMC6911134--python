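"""Nonparametric crossover statistics, correlations and summaries.

The study design is a two-period, two-treatment crossover: every patient
receives both arms (ATC and low PS) in a randomised sequence.  Treatment
is compared by the Wilcoxon signed-rank test on the paired within-patient
differences; the period effect and the treatment-by-period interaction
(carryover) are tested nonparametrically between the two sequence groups
on, respectively, the period differences (y1 - y2) and the subject totals
(y1 + y2).  If the interaction is significant the usual remedy is to keep
period 1 only; if only the period effect is significant the treatment
test is adjusted for period (rank-sum on half period-differences between
sequence groups).

The signed-rank p-value is exact (full enumeration of the null
distribution of W+ via dynamic programming) for n <= 25 pairs without
ties; otherwise a normal approximation with tie and continuity
corrections is used.  No multiple-comparison adjustment is applied
anywhere, matching the analysis plan these tools implement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError, ParameterError

__all__ = [
    "CrossoverDataset",
    "TestResult",
    "wilcoxon_signed_rank",
    "crossover_tests",
    "spearman",
    "sample_size_two_means",
    "median_iqr",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: int
    flag: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise AnalysisError("p-value outside [0, 1]")


@dataclass
class CrossoverDataset:
    """Per-patient paired outcomes with arm sequence.

    ``table`` holds one row per patient with columns ``patient``,
    ``sequence`` (``ATC_first``/``PS_first``) and paired outcome columns
    named ``y_<outcome>_atc`` / ``y_<outcome>_ps``.
    """

    table: pd.DataFrame
    units: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("patient", "sequence"):
            if col not in self.table.columns:
                raise ParameterError(f"missing column {col!r}")

    @property
    def outcomes(self) -> list[str]:
        names = []
        for c in self.table.columns:
            if c.startswith("y_") and c.endswith("_atc"):
                names.append(c[2:-4])
        return names

    def paired(self, outcome: str) -> tuple[np.ndarray, np.ndarray]:
        """(y_atc, y_ps) for patients with both arms present."""
        a = self.table[f"y_{outcome}_atc"].to_numpy(dtype=float)
        p = self.table[f"y_{outcome}_ps"].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(p)
        return a[ok], p[ok]

    def by_sequence(self, outcome: str):
        """Period-ordered values (y1, y2) per sequence group."""
        out = {}
        for seq, sub in self.table.groupby("sequence"):
            a = sub[f"y_{outcome}_atc"].to_numpy(dtype=float)
            p = sub[f"y_{outcome}_ps"].to_numpy(dtype=float)
            ok = np.isfinite(a) & np.isfinite(p)
            a, p = a[ok], p[ok]
            out[seq] = (a, p) if seq == "ATC_first" else (p, a)
        return out


@lru_cache(maxsize=64)
def _signed_rank_pmf(n: int) -> np.ndarray:
    """Exact null counts of W+ over {0..n(n+1)/2} (2^n sign patterns)."""
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] = counts[r:] + counts[:-r]
    return counts / 2.0**n


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (classical treatment).  Exact enumeration
    of the signed-rank null for n <= 25 untied pairs; otherwise normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("paired samples must have equal length")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0,
                          method="wilcoxon-signed-rank", n=0,
                          flag="all differences zero")
    if n < 2:
        return TestResult(statistic=0.0, p_value=1.0,
                          method="wilcoxon-signed-rank", n=n,
                          flag="fewer than 2 non-zero differences")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n

    if n <= 25 and not has_ties:
        pmf = _signed_rank_pmf(n)
        w = int(round(w_plus))
        p_low = float(pmf[: w + 1].sum())
        p_high = float(pmf[w:].sum())
        p = min(1.0, 2.0 * min(p_low, p_high))
        method = "wilcoxon-signed-rank (exact)"
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        if sigma == 0:
            return TestResult(statistic=w_plus, p_value=1.0,
                              method="wilcoxon-signed-rank (approx)", n=n,
                              flag="degenerate")
        diff = w_plus - mu
        z = (diff - 0.5 * np.sign(diff)) / sigma
        p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
        method = "wilcoxon-signed-rank (approx)"
    return TestResult(statistic=w_plus, p_value=p, method=method, n=n)


def _rank_sum(a: np.ndarray, b: np.ndarray, label: str) -> TestResult:
    if a.size == 0 or b.size == 0:
        return TestResult(statistic=0.0, p_value=1.0,
                          method=label, n=a.size + b.size,
                          flag="a sequence group is empty")
    method = "exact" if (a.size + b.size <= 30
                         and np.unique(np.concatenate([a, b])).size
                         == a.size + b.size) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      method=f"{label} (rank-sum, {method})",
                      n=a.size + b.size)


def crossover_tests(data: CrossoverDataset, outcome: str,
                    alpha: float = 0.05) -> dict:
    """Treatment, period and carryover tests for a two-period crossover.

    Returns a dict with :class:`TestResult` entries ``treatment``
    (signed-rank on within-patient differences), ``treatment_adjusted``
    (rank-sum on half period-differences between sequence groups, valid
    under a period effect), ``period`` (rank-sum on period differences
    between sequences), ``carryover`` (rank-sum on subject totals between
    sequences), ``treatment_period1`` (first period only, the fallback
    under carryover) and a human-readable ``decision`` trace.
    """
    y_atc, y_ps = data.paired(outcome)
    if y_atc.size < 2:
        raise AnalysisError("need >= 2 complete patients")
    groups = data.by_sequence(outcome)
    g1 = groups.get("ATC_first", (np.empty(0), np.empty(0)))
    g2 = groups.get("PS_first", (np.empty(0), np.empty(0)))

    treatment = wilcoxon_signed_rank(y_atc, y_ps)
    d1 = g1[0] - g1[1]          # period differences y1 - y2 per sequence
    d2 = g2[0] - g2[1]
    # d1 ~ tau + pi, d2 ~ -tau + pi (tau = ATC-PS, pi = period-1 minus 2):
    # comparing d1 with -d2 isolates pi; comparing d1/2 with d2/2 isolates tau.
    period = _rank_sum(d1, -d2, "period")
    carryover = _rank_sum(g1[0] + g1[1], g2[0] + g2[1], "carryover")
    treatment_adj = _rank_sum(d1 / 2.0, d2 / 2.0, "treatment period-adjusted")
    treatment_p1 = _rank_sum(g1[0], g2[0], "treatment first-period")

    if carryover.p_value < alpha:
        decision = ("treatment-by-period interaction significant: "
                    "use the first period only (treatment_period1)")
    elif period.p_value < alpha:
        decision = ("period effect significant: use the period-adjusted "
                    "treatment test (treatment_adjusted)")
    else:
        decision = "no period or carryover effect: use the paired treatment test"
    return {"treatment": treatment, "treatment_adjusted": treatment_adj,
            "treatment_period1": treatment_p1, "period": period,
            "carryover": carryover, "decision": decision}


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation and its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ParameterError("need at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise AnalysisError("correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def sample_size_two_means(delta: float, sd: float, alpha: float = 0.05,
                          power: float = 0.80) -> int:
    """Patients per group to detect a mean difference ``delta`` (SD ``sd``).

    ``n = ceil(2 * sd^2 * (z_{1-alpha/2} + z_{power})^2 / delta^2)``.
    """
    if delta <= 0 or sd <= 0:
        raise ParameterError("delta and sd must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ParameterError("alpha and power must be in (0, 1)")
    z = sps.norm.ppf(1.0 - alpha / 2.0) + sps.norm.ppf(power)
    return int(math.ceil(2.0 * sd**2 * z**2 / delta**2))


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, Q1, Q3) with quartiles at positions 1 + (n-1)p."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ParameterError("empty input")
    med, q1, q3 = np.percentile(v, [50, 25, 75], method="linear")
    return float(med), float(q1), float(q3)
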