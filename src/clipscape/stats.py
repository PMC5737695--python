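"""Shared statistical primitives: Fisher's exact test, Fisher's method for
combining p-values, Mann-Whitney U and Student's t, with the exact/
approximate policies used throughout the pipeline."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


def fisher_exact_2x2(
    table: list[list[int]] | np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 count table.

    Returns (odds_ratio, p).  Two-sided p uses the point-probability
    method (sum of all fixed-margin tables at most as probable as the
    observed one); "greater" is the enrichment tail of cell [0][0].
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    res = sps.fisher_exact(t, alternative=alternative)
    return float(res[0]), float(res[1])


def odds_ratio_haldane(a: int, b: int, c: int, d: int) -> float:
    """(a*d)/(b*c); 0.5 added to every cell when any cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def combine_fisher(p_list: list[float]) -> tuple[float, int, float]:
    """Combine independent p-values by Fisher's method.

    chi2 = -2 * sum(ln p_i), df = 2m, combined p = upper chi-square tail.
    Zero p-values are clamped to the smallest positive double (warning).
    """
    if len(p_list) == 0:
        raise ValueError("no p-values to combine")
    clean = []
    for p in p_list:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value out of range: {p}")
        if p == 0.0:
            warnings.warn("p=0 clamped to the smallest positive double")
            p = np.finfo(float).tiny
        clean.append(p)
    # sum in sorted order so the statistic is exactly invariant under
    # permutation of the inputs
    chi2 = -2.0 * sum(sorted(math.log(p) for p in clean))
    df = 2 * len(clean)
    return chi2, df, float(sps.chi2.sf(chi2, df))


def mannwhitney_u(
    x, y, alternative: str = "two-sided", exact_max_n: int = 12
) -> tuple[float, float]:
    """Mann-Whitney U test.

    Exact p by enumeration of the permutation distribution when the pooled
    sample size is at most ``exact_max_n`` and there are no ties; otherwise
    the normal approximation with tie correction and continuity correction.
    Returns (U of x, p).  Identical constant samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        u = x.size * y.size / 2.0
        return u, 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= exact_max_n and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class TTestResult:
    statistic: float
    df: float
    p: float
    degenerate: bool = False


def student_t(x, y, equal_var: bool = True) -> TTestResult:
    """Two-sample two-tailed Student's t-test.

    Zero variance in both groups with equal means is degenerate: p = 1 by
    convention, flagged via ``degenerate``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per group")
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        if x.mean() == y.mean():
            return TTestResult(0.0, x.size + y.size - 2, 1.0, degenerate=True)
        return TTestResult(math.inf, x.size + y.size - 2, 0.0, degenerate=True)
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    df = x.size + y.size - 2 if equal_var else float(res.df)
    return TTestResult(float(res.statistic), df, float(res.pvalue))


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation coefficient and its two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of size >= 3")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def ecdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF as (sorted values, cumulative fractions)."""
    v = np.sort(np.asarray(values, dtype=float))
    return v, np.arange(1, v.size + 1) / v.size
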