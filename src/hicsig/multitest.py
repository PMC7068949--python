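"""Shared statistical kernels: binomial upper tail and BH adjustment.

Both background models reduce to the same two primitives: the probability
of observing at least ``n`` successes under a binomial null, and the
rank-based false-discovery-rate adjustment ``q = p * m / r`` followed by
the step-up cumulative minimum.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["binom_sf", "bh_adjust"]

_P_TOL = 1e-12


def binom_sf(n, N, p):
    """P(K >= n) for K ~ Binomial(N, p), numerically stable.

    Vectorized over ``n``; uses the regularized-incomplete-beta survival
    function rather than naive term summation.  ``p`` outside [0, 1] by more
    than 1e-12 is an error; tiny excursions are clamped.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < -_P_TOL) or np.any(p > 1 + _P_TOL):
        raise ValueError("success probability outside [0, 1]")
    p = np.clip(p, 0.0, 1.0)
    n = np.asarray(n)
    if np.any(n < 0):
        raise ValueError("observed count must be >= 0")
    if np.any(n > N):
        raise ValueError("observed count exceeds number of trials")
    # sf(k) = P(K > k), so P(K >= n) = sf(n - 1)
    out = stats.binom.sf(n - 1, N, p)
    if np.ndim(out) == 0:
        return float(out)
    return out


def bh_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values), input order preserved.

    Each p-value is multiplied by ``m`` (the number of comparisons, by
    default the number of tested pairs) and divided by its 1-based ascending
    rank; monotonicity is then enforced by the step-up cumulative minimum
    from the largest rank downward, and values are clamped to <= 1.  Ties
    take ranks in stable input order; the cumulative-minimum step makes tied
    q-values equal regardless.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m cannot be smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, p.size + 1)
    q_sorted = p[order] * m / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def pvalue_ranks(pvalues) -> np.ndarray:
    """1-based ascending ranks with stable tie-breaking, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p, kind="stable")
    ranks = np.empty(p.size, dtype=np.int64)
    ranks[order] = np.arange(1, p.size + 1)
    return ranks
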