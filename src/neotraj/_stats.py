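"""Shared rank-based statistical primitives.

Helpers used by more than one analysis stage: weighted medians and
weighted mid-ranks for the summary-measures machinery, and an exact
permutation p-value for Spearman's rho at small n (the t approximation
is unreliable below ~10 informative points).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats

__all__ = [
    "weighted_median",
    "weighted_midranks",
    "spearman_rho_p",
]


def weighted_median(values, weights) -> float:
    """Lower weighted median: smallest v with cumulative weight >= half the total.

    With unit weights and odd n this is the ordinary median; with even n it is
    the lower of the two central order statistics (deterministic tie rule).
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("weighted_median of empty sequence")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    half = 0.5 * cum[-1]
    # first index whose cumulative weight reaches half
    idx = int(np.searchsorted(cum, half, side="left"))
    return float(v[idx])


def weighted_midranks(values, weights) -> np.ndarray:
    """Mid-ranks where each observation counts with its weight.

    Generalises ordinary mid-ranks: an observation of weight w occupies w
    consecutive "rank slots"; tied observations share the mean of their
    combined slot block.  With unit weights this reduces to
    ``scipy.stats.rankdata(values, method="average")``.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty_like(v)
    cum = 0.0
    i = 0
    vs, ws = v[order], w[order]
    while i < len(vs):
        j = i
        block_w = 0.0
        while j < len(vs) and vs[j] == vs[i]:
            block_w += ws[j]
            j += 1
        # a block of total weight W spanning slots (cum, cum+W] has mid-rank
        # cum + (W+1)/2; with unit weights this is the usual average rank
        mid = cum + (block_w + 1.0) / 2.0
        ranks[order[i:j]] = mid
        cum += block_w
        i = j
    return ranks


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho by full enumeration.

    Enumerates all n! pairings of the (possibly tied) rank vectors.  rho is a
    linear function of sum(rx * ry[perm]), so only that dot product varies.
    """
    n = len(rx)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    denom = math.sqrt(float(np.sum(sx**2)) * float(np.sum(sy**2)))
    if denom == 0:
        return float("nan")
    s_obs = abs(rho_obs)
    count = 0
    total = 0
    chunk = 200_000
    it = itertools.permutations(sy)
    while True:
        block = np.array(list(itertools.islice(it, chunk)))
        if block.size == 0:
            break
        rhos = block @ sx / denom
        count += int(np.sum(np.abs(rhos) >= s_obs - 1e-12))
        total += block.shape[0]
        if block.shape[0] < chunk:
            break
    return count / total


def spearman_rho_p(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman rho with mid-rank ties and a two-sided p-value.

    Exact permutation enumeration for n <= ``exact_max_n``; the t
    approximation (scipy's default) above that.
    Returns (nan, nan) if either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be the same length")
    if len(x) < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if len(x) <= exact_max_n:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        p = _exact_spearman_p(rx, ry, rho)
    else:
        p = float(res.pvalue)
    return rho, p
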