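"""Exact and classical statistics shared by every analysis stage.

The central primitive is a two-sided Fisher's exact test on a 2x2 table of
methylated/unmethylated call counts, computed with the minimum-likelihood
rule: the p-value is the sum of hypergeometric point probabilities, over all
tables with the observed margins, that are no larger than the probability of
the observed table. Small tables are evaluated in exact integer arithmetic so
the result is correct to floating-point precision; very large pooled tables
fall back to :func:`scipy.stats.fisher_exact`, which applies the same rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact_2x2",
    "chi_square_gof",
    "welch_t",
    "pearson_r",
    "proportion_pct",
    "ChiSquareResult",
    "TTestResult",
]

# above this grand total the exact integer path is needlessly slow; scipy's
# float implementation of the same two-sided rule takes over
_EXACT_TOTAL_LIMIT = 500

# smallest positive double; p-values are clamped into (0, 1]
_P_FLOOR = 5e-324


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for two samples: row 1 = (methylated, unmethylated) of sample A,
    row 2 = sample B."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"table entry {name}={v!r} must be a non-negative integer")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero contingency table")


def _as_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    arr = np.asarray(table).reshape(4)
    return ContingencyTable2x2(*(int(x) for x in arr))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 table.

    Accepts a :class:`ContingencyTable2x2`, a flat ``(a, b, c, d)`` sequence,
    or a 2x2 array-like. Returns a probability in ``(0, 1]``.
    """
    t = _as_table(table)
    a, b, c, d = t.a, t.b, t.c, t.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        # degenerate margin: the observed table is the only table
        return 1.0
    if n > _EXACT_TOTAL_LIMIT:
        p = float(_sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        return min(1.0, max(p, _P_FLOOR))

    # exact path: point probability of table with k in cell (1,1) is
    # C(r1,k) C(r2,c1-k) / C(n,c1); compare integer weights, divide once
    kmin = max(0, c1 - r2)
    kmax = min(r1, c1)
    w_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    num = 0
    for k in range(kmin, kmax + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        if w <= w_obs:
            num += w
    denom = math.comb(n, c1)
    if num >= denom:
        return 1.0
    # integer ratio -> float, exactly rounded
    p = num / denom
    return max(p, _P_FLOOR)


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float

    def __iter__(self):
        return iter((self.chi2, self.df, self.p))


def chi_square_gof(observed: Sequence[float], expected_ratio: Sequence[float]) -> ChiSquareResult:
    """Pearson goodness-of-fit chi-square, no continuity correction.

    ``observed`` are category counts; ``expected_ratio`` are positive weights
    defining the null proportions (e.g. ``(1, 1)`` for 1:1 segregation).
    """
    obs = np.asarray(observed, dtype=float)
    w = np.asarray(expected_ratio, dtype=float)
    if obs.shape != w.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("observed and expected_ratio must be 1-d sequences of equal length >= 2")
    if obs.sum() <= 0:
        raise ValueError("total observed count must be positive")
    if np.any(obs < 0):
        raise ValueError("negative observed count")
    if np.any(w <= 0):
        raise ValueError("expected weights must be positive (zero expected count)")
    expected = obs.sum() * w / w.sum()
    chi2 = float(np.sum((obs - expected) ** 2 / expected))
    df = len(obs) - 1
    p = float(_sps.chi2.sf(chi2, df))
    return ChiSquareResult(chi2, df, p)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float

    def __iter__(self):
        return iter((self.t, self.df, self.p))


def welch_t(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) < 2 or len(ya) < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(xa) == 0 or np.var(ya) == 0:
        raise ValueError("degenerate sample: zero variance")
    res = _sps.ttest_ind(xa, ya, equal_var=False)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("length mismatch")
    if len(xa) < 3:
        raise ValueError("need at least 3 paired values")
    if np.var(xa) == 0 or np.var(ya) == 0:
        raise ValueError("zero variance")
    return float(_sps.pearsonr(xa, ya)[0])


def proportion_pct(success: int, failure: int) -> float:
    """Percentage ``100 * success / (success + failure)``.

    Display convention downstream is one decimal place; the full-precision
    value is returned.
    """
    if success < 0 or failure < 0:
        raise ValueError("counts must be non-negative")
    total = success + failure
    if total == 0:
        raise ValueError("zero total")
    return 100.0 * success / total
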