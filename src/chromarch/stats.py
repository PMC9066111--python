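"""Shared statistical engine: vectorized exact binomial test and BH adjustment.

The differential-interaction and DMR callers both test pooled treated counts
x against n = x_t + x_c with a library-size null proportion, so the two-sided
exact binomial test has to run on 10^5–10^6 pairs at once. The implementation
below computes the minimum-likelihood two-sided p-value (the same definition
scipy.stats.binomtest uses) fully vectorized: the binomial pmf is unimodal,
so the opposite tail cutoff is found by binary search on the monotone flank.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

# relative tolerance when comparing pmf values, matching scipy's convention
_RELERR = 1 + 1e-7


def binom_test_two_sided(x, n, p0: float) -> np.ndarray:
    """Two-sided exact binomial p-values for observing x successes out of n.

    Parameters
    ----------
    x, n : array-like of non-negative ints (broadcastable)
    p0 : null success probability in (0, 1)

    Returns p-values in [0, 1]; n == 0 yields 1.
    """
    x = np.atleast_1d(np.asarray(x, dtype=np.int64))
    n = np.broadcast_to(np.asarray(n, dtype=np.int64), x.shape).copy()
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0, 1)")
    if np.any(x < 0) or np.any(x > n):
        raise ValueError("require 0 <= x <= n")

    p = np.ones(x.shape, dtype=float)
    mode = np.floor(p0 * (n + 1)).astype(np.int64)
    mode = np.minimum(mode, n)
    pmf_x = binom.pmf(x, n, p0)
    thresh = pmf_x * _RELERR

    left = x < mode   # add right tail beyond a cutoff y >= mode
    right = x > mode  # add left tail up to a cutoff y <= mode

    if np.any(left):
        xi, ni, th = x[left], n[left], thresh[left]
        lo = mode[left].copy()
        hi = ni + 1
        # first y in [mode, n] with pmf(y) <= thresh (pmf decreasing there);
        # lo == n+1 if none, giving an empty right tail
        while np.any(lo < hi):
            mid = (lo + hi) // 2
            act = lo < hi
            take = np.zeros(lo.shape, dtype=bool)
            take[act] = binom.pmf(mid[act], ni[act], p0) <= th[act]
            hi = np.where(act & take, mid, hi)
            lo = np.where(act & ~take, mid + 1, lo)
        pv = binom.cdf(xi, ni, p0) + binom.sf(lo - 1, ni, p0)
        pv = np.where(lo > ni, binom.cdf(xi, ni, p0), pv)
        p[left] = pv

    if np.any(right):
        xi, ni, th = x[right], n[right], thresh[right]
        lo = np.zeros(xi.shape, dtype=np.int64)
        hi = mode[right].copy()
        # first y in [0, mode] with pmf(y) > thresh (pmf increasing there);
        # the left tail then runs up to y - 1
        while np.any(lo < hi):
            mid = (lo + hi) // 2
            act = lo < hi
            take = np.zeros(lo.shape, dtype=bool)
            take[act] = binom.pmf(mid[act], ni[act], p0) > th[act]
            hi = np.where(act & take, mid, hi)
            lo = np.where(act & ~take, mid + 1, lo)
        tail = np.where(lo > 0, binom.cdf(lo - 1, ni, p0), 0.0)
        p[right] = binom.sf(xi - 1, ni, p0) + tail

    return np.clip(p, 0.0, 1.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
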