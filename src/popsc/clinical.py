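"""Clinical characteristics table statistics.

The cohort-description tests used for baseline clinical variables: a pooled
two-sample Student t-test (from raw values or published n/mean/SD summaries),
the exact two-sided Mann-Whitney U test, and two-sided 2x2 categorical tests
(Fisher exact with the point-probability rule, and Pearson chi-square with
optional Yates correction). A dispatcher mirrors the common crosstabs
convention of preferring the exact test when any expected cell count is
below 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

EXACT_MAX_N = 12


@dataclass(frozen=True)
class SummaryStats:
    """n, mean and sample SD of one group (SD uses the n-1 denominator)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("summary requires n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_raw(cls, values) -> "SummaryStats":
        values = np.asarray(values, dtype=float)
        return cls(n=values.size, mean=float(values.mean()), sd=float(values.std(ddof=1)))


def pooled_t_test(g1, g2) -> tuple[float, int, float]:
    """Two-tailed pooled-variance Student t-test.

    Accepts :class:`SummaryStats` or raw value vectors for either group.
    Returns (t, df, two-tailed p).
    """
    if not isinstance(g1, SummaryStats):
        g1 = SummaryStats.from_raw(g1)
    if not isinstance(g2, SummaryStats):
        g2 = SummaryStats.from_raw(g2)
    res = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=True
    )
    return float(res.statistic), g1.n + g2.n - 2, float(res.pvalue)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when n_x + n_y <= 12 with no ties, otherwise the
    tie-corrected normal approximation with continuity correction.
    Returns (U of x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires nonempty samples")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass(frozen=True)
class Table2x2:
    """2x2 contingency table; rows are groups, columns outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(v < 0 for v in cells) or any(v != int(v) for v in cells):
            raise ValueError("cell counts must be non-negative integers")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact_2x2(t: Table2x2) -> float:
    """Two-sided Fisher exact p: sum over margin-preserving tables whose
    hypergeometric point probability does not exceed the observed one.
    An all-zero table is degenerate and returns p = 1."""
    if t.total == 0:
        return 1.0
    _, p = stats.fisher_exact(t.to_array(), alternative="two-sided")
    return float(min(p, 1.0))


def chi2_2x2(t: Table2x2, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square test on a 2x2 table with optional Yates correction."""
    table = t.to_array()
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square test requires positive margins")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)


def categorical_test(t: Table2x2) -> tuple[str, float]:
    """Fisher exact when any expected cell count is < 5, else Pearson chi-square.

    Returns (test name, two-sided p).
    """
    table = t.to_array().astype(float)
    if t.total == 0:
        return "fisher", 1.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / t.total
    if (expected < 5).any():
        return "fisher", fisher_exact_2x2(t)
    return "chi2", chi2_2x2(t)[1]
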