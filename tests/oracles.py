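"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: exact integer /
Fraction arithmetic for Fisher's test, exhaustive permutation
enumeration for the rank-sum test, direct log-likelihood evaluation for
the binomial LRT, and per-offset rescoring for PWM scans.
"""

from fractions import Fraction
from itertools import combinations
from math import comb, log

import numpy as np

# same two-sided inclusion tolerance as the implementation (R convention)
REL_TOL = Fraction(1, 10**7)


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact rational hypergeometric enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    r2 = c + d
    lo, hi = max(0, c1 - r2), min(r1, c1)
    # P(X = x) = C(r1, x) C(r2, c1 - x) / C(n, c1); compare numerators only
    nums = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    denom = comb(n, c1)
    cutoff = Fraction(nums[a]) * (1 + REL_TOL)
    total = sum(v for v in nums.values() if Fraction(v) <= cutoff)
    return float(min(Fraction(1), Fraction(total, denom)))


def hypergeom_upper_tail_exact(overlap: int, universe: int, set_size: int, query: int) -> float:
    """P(X >= overlap) by direct rational tail summation."""
    hi = min(set_size, query)
    total = sum(
        Fraction(comb(set_size, x) * comb(universe - set_size, query - x), comb(universe, query))
        for x in range(overlap, hi + 1)
    )
    return float(total)


def ranksum_two_sided_exact(x, y) -> float:
    """Exhaustive-permutation two-sided Mann-Whitney p (tie-free data).

    Enumerates every assignment of pooled ranks to the first group and
    doubles the smaller tail (capped at 1), the same convention the
    exact implementation uses.
    """
    x, y = list(x), list(y)
    nx, ny = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - nx * (nx + 1) // 2
    us = []
    all_ranks = list(range(1, nx + ny + 1))
    for grp in combinations(all_ranks, nx):
        us.append(sum(grp) - nx * (nx + 1) // 2)
    us = np.array(us)
    n_tot = len(us)
    p_le = np.sum(us <= u_obs) / n_tot
    p_ge = np.sum(us >= u_obs) / n_tot
    return float(min(1.0, 2 * min(p_le, p_ge)))


def lrt_binomial_direct(inc1: int, tot1: int, inc2: int, tot2: int) -> float:
    """Binomial LRT p by direct log-likelihood evaluation + chi2 survival."""
    from scipy.stats import chi2

    def ll(k, n, p):
        if p <= 0 or p >= 1:
            p = min(max(p, 1e-12), 1 - 1e-12)
        return k * log(p) + (n - k) * log(1 - p)

    f1, f2 = inc1 / tot1, inc2 / tot2
    f0 = (inc1 + inc2) / (tot1 + tot2)
    stat = 2 * (ll(inc1, tot1, f1) + ll(inc2, tot2, f2) - ll(inc1, tot1, f0) - ll(inc2, tot2, f0))
    return float(chi2.sf(max(stat, 0.0), 1))


def bh_stepup_direct(pvals):
    """Hand-rolled BH step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top  # 1-based rank of this p-value
        val = min(prev, p[idx] * m / i)
        adj[idx] = val
        prev = val
    return adj


def scan_pwm_bruteforce(seq: str, matrix: np.ndarray, background: np.ndarray, threshold_frac: float = 0.8):
    """Per-offset PWM rescoring with plain Python dict lookups."""
    lut = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = matrix.shape[0]
    lo = np.log2((matrix + 1e-6) / (background + 1e-6))
    max_score = float(lo.max(axis=1).sum())
    hits = []
    for i in range(len(seq) - L + 1):
        window = seq[i : i + L].upper()
        if any(ch not in lut for ch in window):
            continue
        score = sum(lo[j, lut[window[j]]] for j in range(L))
        if score >= threshold_frac * max_score:
            hits.append((i, score))
    return hits
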