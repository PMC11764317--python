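"""Exact 2×2 co-occurrence testing of patient-level mutation statuses.

With cohorts of a few dozen patients the cells are small, so the two-sided
Fisher exact test (probability-ordering definition: sum the hypergeometric
probabilities of all tables with the observed margins that are no more
probable than the observed one) is the default; a Pearson chi-square without
continuity correction is available for comparison.  Hypergeometric terms are
evaluated in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .errors import ValidationError

# Relative slack when comparing table probabilities to the observed one, so
# ties produced by floating-point rounding are included in the tail.
_REL_TOL = 1e-7


@dataclass
class ContingencyResult:
    table: np.ndarray  # 2×2 int, rows = status_a (False, True), cols = status_b
    odds_ratio: float
    p_two_sided: float
    method: str = "fisher"


def build_2x2(
    status_a: Mapping[str, bool], status_b: Mapping[str, bool]
) -> np.ndarray:
    """Cross-tabulate two boolean patient maps over the same patient universe.

    Orientation: rows index status_a (absent, present), columns status_b, so
    the cells read (a−b−, a−b+ / a+b−, a+b+).
    """
    only = set(status_a) ^ set(status_b)
    if only:
        raise ValidationError(
            f"patient(s) present in only one status map: {', '.join(sorted(only))}"
        )
    table = np.zeros((2, 2), dtype=int)
    for p in status_a:
        table[int(bool(status_a[p])), int(bool(status_b[p]))] += 1
    return table


def _log_hypergeom(a: int, r1: int, r2: int, c1: int, n: int) -> float:
    """log P(top-left cell = a) for fixed margins r1, r2 (rows), c1 (column), n."""
    return (
        gammaln(r1 + 1)
        - gammaln(a + 1)
        - gammaln(r1 - a + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - a + 1)
        - gammaln(r2 - c1 + a + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


def _odds_ratio(table: np.ndarray) -> float:
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    if min(a + b, c + d, a + c, b + d) == 0:
        return float("nan")  # a whole margin is empty; OR undefined
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def fisher_exact_2x2(table: np.ndarray | Sequence[Sequence[int]]) -> ContingencyResult:
    """Two-sided Fisher exact test by full enumeration over the margin."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError("expected a 2×2 table")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValidationError("cells must be non-negative integers")
    t = t.astype(int)
    if t.sum() == 0:
        raise ValidationError("table total must be positive")
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    n = r1 + r2
    a_obs = int(t[0, 0])
    lp_obs = _log_hypergeom(a_obs, r1, r2, c1, n)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = 0.0
    for a in range(lo, hi + 1):
        lp = _log_hypergeom(a, r1, r2, c1, n)
        if lp <= lp_obs + math.log1p(_REL_TOL):
            total += math.exp(lp)
    return ContingencyResult(
        table=t,
        odds_ratio=_odds_ratio(t),
        p_two_sided=min(1.0, total),
        method="fisher",
    )


def chi_square_2x2(table: np.ndarray | Sequence[Sequence[int]]) -> ContingencyResult:
    """Pearson chi-square without continuity correction, for comparison."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("expected a non-negative 2×2 table")
    _, p, _, _ = stats.chi2_contingency(t, correction=False)
    return ContingencyResult(
        table=t, odds_ratio=_odds_ratio(t), p_two_sided=float(p), method="chi2"
    )
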