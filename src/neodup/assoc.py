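"""Contingency-table statistics: goodness-of-fit χ², Yates 2×2 χ², Fisher exact.

The Yates-corrected statistic uses the clamped continuity correction
Σ (max(|O−E|−0.5, 0))²/E, which guarantees a nonnegative statistic and a
value of exactly 0 on perfectly proportional tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class ContingencyResult:
    statistic: float
    df: int
    p: float
    correction: bool = False


def chisq_gof(observed, expected="equal") -> ContingencyResult:
    """Goodness-of-fit χ² of observed counts against expected proportions.

    ``expected="equal"`` tests a uniform split.  No continuity correction;
    df = k − 1.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.sum() <= 0:
        raise ValueError("observed counts must sum to a positive total")
    if isinstance(expected, str) and expected == "equal":
        exp = np.full_like(obs, obs.sum() / obs.size)
    else:
        exp = np.asarray(expected, dtype=float)
        exp = exp * obs.sum() / exp.sum()
    if np.any(exp <= 0):
        raise ValueError("expected counts must all be positive")
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1
    return ContingencyResult(chi2, df, float(stats.chi2.sf(chi2, df)), False)


def chisq_2x2(a: float, b: float, c: float, d: float, yates: bool = True) -> ContingencyResult:
    """2×2 independence χ² for the table [[a, b], [c, d]], Yates-corrected by default."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    total = obs.sum()
    if np.any(rows <= 0) or np.any(cols <= 0):
        raise ValueError("all row and column margins must be positive")
    exp = np.outer(rows, cols) / total
    dev = np.abs(obs - exp)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / exp).sum())
    return ContingencyResult(chi2, 1, float(stats.chi2.sf(chi2, 1)), yates)


def chisq_2x2_yates(a: float, b: float, c: float, d: float) -> ContingencyResult:
    return chisq_2x2(a, b, c, d, yates=True)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed that of the observed table.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if min(a + b, c + d, a + c, b + d) <= 0:
        raise ValueError("all margins must be positive")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)
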