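"""Shared exact-test and multiple-testing primitives.

All 2x2 enrichment comparisons in the package go through
:func:`fisher_exact_2x2`, which computes the two-sided p-value by
hypergeometric tail summation (the same convention as R's ``fisher.test``:
every table whose probability does not exceed that of the observed table,
up to a small relative tolerance, contributes to the p-value).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

# Relative tolerance when comparing point probabilities for two-sided
# summation; matches the convention used by R's fisher.test.
_REL_TOL = 1e-7


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_pmf_vector(n: int, r1: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and pmf of the hypergeometric count in cell (1,1).

    The table has row sums (r1, n - r1) and column sums (c1, n - c1).
    """
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = _log_comb(r1, support) + _log_comb(n - r1, c1 - support) - _log_comb(n, c1)
    return support, np.exp(logpmf)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the table [[a, b], [c, d]].

    Conditions on both margins; sums hypergeometric point probabilities
    not exceeding that of the observed table.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1 = a + b
    c1 = a + c
    support, pmf = hypergeom_pmf_vector(n, r1, c1)
    p_obs = pmf[a - support[0]]
    p = float(pmf[pmf <= p_obs * (1.0 + _REL_TOL)].sum())
    return min(1.0, p)


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio a*d / (b*c); inf when b*c == 0 and a*d > 0."""
    num = a * d
    den = b * c
    if den == 0:
        return np.inf if num > 0 else np.nan
    return num / den


def hypergeom_upper_tail(overlap: int, universe: int, set_size: int, query_size: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, set_size, query_size)."""
    if overlap < 0:
        raise ValueError("overlap must be non-negative")
    return float(sps.hypergeom.sf(overlap - 1, universe, set_size, query_size))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries are passed through untouched and do not count toward the
    number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() == 0:
        return q
    q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def ranksum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Uses the exact null distribution when n*m <= 400 and the data are
    tie-free, otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if has_ties or x.size * y.size > 400:
        method = "asymptotic"
    else:
        method = "exact"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
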