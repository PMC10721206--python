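"""Shared exact statistical primitives.

Two routines are implemented by hand because their contracts demand exact
small-sample behaviour that float-based library shortcuts cannot guarantee:

* :func:`rank_sum_test` — two-sided Wilcoxon rank-sum with exhaustive
  enumeration of all rank splits (midranks for ties) when the combined
  sample size is <= ``exact_max_n``, and the tie-corrected normal
  approximation (with continuity correction) above it.
* :func:`fisher_two_sided` — Fisher's exact test by the minimum-likelihood
  rule, summing the probabilities of all tables (at fixed margins) that are
  no more likely than the observed one.  All arithmetic is exact integer
  arithmetic, so ties in the hypergeometric weights are resolved exactly.
"""

from __future__ import annotations

import math
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = ["rank_sum_test", "fisher_two_sided"]


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def rank_sum_test(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 20
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of ``x`` vs ``y``.

    Returns (W, p) where W is the rank sum of ``x``.  For combined sample
    sizes up to ``exact_max_n`` the null distribution of W is enumerated
    over every split of the pooled midranks; the two-sided p doubles the
    smaller tail (capped at 1).  Larger samples use the tie-corrected
    normal approximation with continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w_obs = float(ranks[:n1].sum())
    n = n1 + n2
    if n <= exact_max_n:
        tol = 1e-9
        n_le = n_ge = total = 0
        for idx in combinations(range(n), n1):
            w = ranks[list(idx)].sum()
            total += 1
            if w <= w_obs + tol:
                n_le += 1
            if w >= w_obs - tol:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        return w_obs, p
    # Normal approximation with tie correction and continuity correction.
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return w_obs, float(res.pvalue)


def fisher_two_sided(table) -> tuple[float, float]:
    """Fisher's exact test (minimum-likelihood two-sided rule) on a 2x2 table.

    Returns (odds_ratio, p).  The odds ratio is the sample cross-product
    ratio a*d / (b*c); when any cell is zero a Haldane 0.5 continuity
    correction is applied to every cell (the caller should flag this).
    The p-value is exact: hypergeometric weights are compared as integers.
    """
    (a, b), (c, d) = (int(table[0][0]), int(table[0][1])), (
        int(table[1][0]),
        int(table[1][1]),
    )
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if a + b + c + d == 0:
        raise ValueError("empty table")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    r1 = a + b
    c1 = a + c
    n = a + b + c + d
    weights = _hypergeom_weights(n, r1, c1)
    lo = max(0, r1 + c1 - n)
    w_obs = weights[a - lo]
    total = sum(weights)
    p_num = sum(w for w in weights if w <= w_obs)
    return float(odds), p_num / total


@lru_cache(maxsize=1 << 18)
def _hypergeom_weights(n: int, r1: int, c1: int) -> tuple[int, ...]:
    """Integer weights C(r1, x) * C(n - r1, c1 - x) over the support of x."""
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    return tuple(
        math.comb(r1, x) * math.comb(n - r1, c1 - x) for x in range(lo, hi + 1)
    )
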