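"""Small-sample categorical and correlation statistics, written from formulas.

The core inferential steps behind categorical texture comparisons and
left/right modulus association are deliberately implemented from their
defining formulas rather than wrapped from a stats library, so the exact
computational variant is pinned down:

* Pearson chi-squared on a 2x2 table WITHOUT Yates continuity correction —
  the uncorrected statistic is the variant that small published tables of
  group-vs-feature counts reproduce exactly;
* product-moment (Pearson) correlation;
* Spearman correlation as Pearson on mid-ranks (ties averaged).

p-values are provided for display from the chi2(1) and t distributions.
Routine group-comparison conveniences (t-test, Mann-Whitney) are thin,
clearly labelled wrappers over scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _scipy_stats

__all__ = [
    "ContingencyTable2x2",
    "chi2_2x2",
    "chi2_pvalue",
    "pearson_r",
    "spearman_r",
    "correlation_pvalue",
    "ttest_ind",
    "mannwhitney",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for two groups (rows) by feature present/absent (columns)."""

    a: int  # group 1, feature present
    b: int  # group 1, feature absent
    c: int  # group 2, feature present
    d: int  # group 2, feature absent

    def __post_init__(self) -> None:
        for name, v in (("a", self.a), ("b", self.b), ("c", self.c), ("d", self.d)):
            if int(v) != v or v < 0:
                raise ValueError(f"count {name} must be a non-negative integer")
        if self.total == 0:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_flags(cls, group1_flags, group2_flags) -> "ContingencyTable2x2":
        """Build from boolean feature flags of the two groups."""
        g1 = np.asarray(group1_flags, dtype=bool)
        g2 = np.asarray(group2_flags, dtype=bool)
        return cls(
            a=int(g1.sum()),
            b=int((~g1).sum()),
            c=int(g2.sum()),
            d=int((~g2).sum()),
        )

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def chi2_2x2(table: ContingencyTable2x2) -> tuple[float, int]:
    """Pearson chi-squared statistic of a 2x2 table, no continuity correction.

    Returns ``(statistic, df)`` with df = 1.  Expected counts come from the
    row/column marginals; a zero marginal leaves the statistic undefined and
    raises.
    """
    obs = table.as_array()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("chi-squared undefined: a row or column marginal is zero")
    expected = np.outer(row, col) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    return stat, 1


def chi2_pvalue(statistic: float, df: int = 1) -> float:
    """Upper-tail chi-squared p-value (display only)."""
    return float(_scipy_stats.chi2.sf(statistic, df))


def _validate_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("correlation requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return x, y


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient.

    r = sum((x - xbar)(y - ybar)) / sqrt(sum((x - xbar)^2) sum((y - ybar)^2))
    """
    x, y = _validate_xy(x, y)
    dx = x - x.mean()
    dy = y - y.mean()
    return float((dx @ dy) / math.sqrt((dx @ dx) * (dy @ dy)))


def _midranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties given the average of the tied positions."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size, dtype=float)
    sx = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman_r(x, y) -> float:
    """Spearman rank correlation: Pearson on mid-ranks (ties averaged)."""
    x, y = _validate_xy(x, y)
    return pearson_r(_midranks(x), _midranks(y))


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a correlation via the t transform (display only)."""
    if n < 3:
        raise ValueError("need at least 3 observations")
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * _scipy_stats.t.sf(abs(t), n - 2))


# -- routine group-comparison conveniences (thin scipy wrappers) -----------

def ttest_ind(x, y, equal_var: bool = True) -> tuple[float, float]:
    """Convenience wrapper: independent two-sample t-test (scipy)."""
    res = _scipy_stats.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def mannwhitney(x, y) -> tuple[float, float]:
    """Convenience wrapper: Mann-Whitney U test, two-sided (scipy)."""
    res = _scipy_stats.mannwhitneyu(np.asarray(x, float), np.asarray(y, float), alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
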