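"""Shared statistical primitives for the pipeline.

Benjamini–Hochberg FDR adjustment, two-sided Fisher's exact and chi-square
tests on 2x2 tables, the classical (pooled-variance) two-sample Student
t-test, and a numerically stable upper binomial tail.  All heavy lifting is
delegated to scipy/statsmodels; this module pins down the exact conventions
the pipeline relies on (two-sided Fisher by the point-probability rule,
chi-square without Yates correction by default, degenerate-variance t-test
behaviour).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TwoByTwoTable",
    "TestResult",
    "bh_fdr",
    "fisher_exact_two_sided",
    "chi_square_2x2",
    "student_t_two_sample",
    "binomial_tail_geq",
]


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts of a 2x2 contingency table.

    In the enrichment context: ``a`` = listed genes in the term, ``b`` =
    listed genes outside the term, ``c`` = background-only genes in the
    term, ``d`` = background-only genes outside the term.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"table entry {name!r} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


class TestResult(NamedTuple):
    statistic: float
    pvalue: float


def _as_table(t: TwoByTwoTable | Sequence[int]) -> TwoByTwoTable:
    if isinstance(t, TwoByTwoTable):
        return t
    vals = list(t)
    if len(vals) != 4:
        raise ValueError("expected a TwoByTwoTable or a sequence of four counts")
    return TwoByTwoTable(*vals)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted q-values, in the input order.

    q_i = min over j with p_j >= p_i of (m * p_j / rank_j), clipped to 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-d vector")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact_two_sided(t: TwoByTwoTable | Sequence[int]) -> float:
    """Two-sided Fisher exact p-value by the point-probability rule.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose point probability does not exceed that of the observed
    table (the conventional two-sided definition).
    """
    t = _as_table(t)
    return float(_sps.fisher_exact(t.as_array(), alternative="two-sided")[1])


def chi_square_2x2(t: TwoByTwoTable | Sequence[int], *, yates: bool = False) -> TestResult:
    """Pearson chi-square test on a 2x2 table (1 df), no continuity
    correction unless ``yates=True``.

    Raises if a margin is zero (the expected counts vanish); Fisher's exact
    test handles those tables.
    """
    t = _as_table(t)
    arr = t.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("2x2 table has a zero margin; use fisher_exact_two_sided instead")
    res = _sps.chi2_contingency(arr, correction=yates)
    return TestResult(float(res.statistic), float(res.pvalue))


def student_t_two_sample(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Classical pooled-variance two-sample t-test, two-sided.

    Degenerate case (zero pooled variance): p = 1 when the means agree,
    p = 0 when they differ — both samples are then constant, so the data
    are either perfectly consistent or perfectly inconsistent with the
    null of equal means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    sx2 = x.var(ddof=1)
    sy2 = y.var(ddof=1)
    if sx2 == 0.0 and sy2 == 0.0:
        diff = x.mean() - y.mean()
        if diff == 0.0:
            return TestResult(0.0, 1.0)
        return TestResult(float(np.sign(diff)) * np.inf, 0.0)
    stat, p = _sps.ttest_ind(x, y, equal_var=True)
    return TestResult(float(stat), float(p))


def binomial_tail_geq(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), stable for small p and large n."""
    if not (0 <= k <= n):
        raise ValueError(f"k must satisfy 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if k == 0:
        return 1.0
    return float(_sps.binom.sf(k - 1, n, p))
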