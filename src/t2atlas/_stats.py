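"""Shared statistical primitives: rank-sum test, exact binomial test, BH.

The Wilcoxon rank-sum implementation carries its own exact small-sample path
because the marker contract requires exact p-values in the presence of ties
(log-normalized expression vectors are full of zeros), which off-the-shelf
exact routines refuse.  The exact null is computed by a tie-aware
subset-sum convolution over midranks; for larger groups a normal
approximation with the standard tie correction is used (no continuity
correction).  Two-sided p-values are ``min(1, 2 * min(lower, upper))`` in
both paths.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom, norm, rankdata
from statsmodels.stats.multitest import multipletests

__all__ = ["rank_sum_test", "binom_test_two_sided", "bh_adjust"]

#: Largest group size for which the exact rank-sum null is enumerated.
EXACT_MAX_GROUP = 8


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value for samples ``x`` vs ``y``.

    Exact (tie-aware) when both groups have at most ``EXACT_MAX_GROUP``
    observations, otherwise normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    w = ranks[:n1].sum()
    if n1 <= EXACT_MAX_GROUP and n2 <= EXACT_MAX_GROUP:
        return _exact_rank_sum_p(ranks, n1, w)
    return _asymptotic_rank_sum_p(ranks, n1, n2, w)


def _asymptotic_rank_sum_p(ranks, n1, n2, w) -> float:
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values identical
        return 1.0
    z = (w - mu) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def _exact_rank_sum_p(ranks, n1, w) -> float:
    # Doubled midranks are integers; count size-n1 subsets by sum with a
    # 2-D subset-sum convolution, then read off both tails.
    s = np.asarray(np.round(2 * ranks), dtype=np.int64)
    total = int(s.sum())
    # dp[k, v] = number of subsets of size k with doubled-rank sum v
    dp = np.zeros((n1 + 1, total + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for si in s:
        dp[1:, si:] += dp[:-1, : total + 1 - si]
    dist = dp[n1]
    n_subsets = dist.sum()
    w2 = int(round(2 * w))
    lower = dist[: w2 + 1].sum() / n_subsets
    upper = dist[w2:].sum() / n_subsets
    return float(min(1.0, 2.0 * min(lower, upper)))


def binom_test_two_sided(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial p-value, minimum-tail-doubling convention."""
    if not 0 <= k <= n:
        raise ValueError("k out of range")
    lower = binom.cdf(k, n, p)
    upper = binom.sf(k - 1, n, p)
    return float(min(1.0, 2.0 * min(lower, upper)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (empty input passes through)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
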