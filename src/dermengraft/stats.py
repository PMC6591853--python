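"""Rank-based two-sample testing and false-discovery-rate control.

Self-contained implementations of the Wilcoxon-Mann-Whitney rank-sum test
(exact null distribution for small untied samples, normal approximation with
tie and continuity corrections otherwise) and Benjamini-Hochberg step-up
adjustment.  Kept independent of scipy's ``mannwhitneyu`` and statsmodels'
``multipletests`` so those remain available as external cross-checks.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["rank_sum_test", "bh_adjust"]

#: largest group size for which the exact U distribution is enumerated
EXACT_LIMIT = 25


@lru_cache(maxsize=2048)
def _u_counts(m: int, n: int) -> np.ndarray:
    """Counts of the Mann-Whitney U null distribution for group sizes m, n.

    ``_u_counts(m, n)[u]`` is the number of the C(m+n, m) equally likely rank
    arrangements yielding statistic u; recurrence
    N(u; m, n) = N(u - n; m - 1, n) + N(u; m, n - 1).
    Exact in float64 for m, n <= 25 (max count < 2^53).
    """
    if m == 0 or n == 0:
        out = np.ones(1)
    else:
        out = np.zeros(m * n + 1)
        a = _u_counts(m - 1, n)
        b = _u_counts(m, n - 1)
        out[n:n + len(a)] += a
        out[: len(b)] += b
    out.setflags(write=False)
    return out


def rank_sum_test(
    x,
    y,
    method: str = "auto",
    use_continuity: bool = True,
) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney rank-sum test.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of ``x``.
    ``method``: ``"exact"`` enumerates the null distribution (requires no
    ties), ``"asymptotic"`` uses the normal approximation with tie correction
    and (optionally) continuity correction, ``"auto"`` picks exact when both
    groups have < 25 observations and the pooled sample is tie-free.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u1 = float(ranks[:m].sum() - m * (m + 1) / 2)
    has_ties = len(np.unique(pooled)) < m + n
    if method == "exact" or (method == "auto" and not has_ties
                             and m < EXACT_LIMIT and n < EXACT_LIMIT):
        if has_ties:
            raise ValueError("exact method is undefined with ties")
        counts = _u_counts(m, n)
        total = counts.sum()
        u = int(round(u1))
        cdf = counts[: u + 1].sum() / total
        sf = counts[u:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
        return u1, float(p)
    # normal approximation
    mu = m * n / 2.0
    N = m + n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    var = m * n / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:  # everything tied
        return u1, 1.0
    num = u1 - mu
    if use_continuity:
        num = np.sign(num) * max(abs(num) - 0.5, 0.0)
    z = num / np.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return u1, float(min(p, 1.0))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * n / j over the ascending order statistics;
    NaN entries are passed through and excluded from the family size.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    nn = pv.size
    if nn == 0:
        return q
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * nn / np.arange(1, nn + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    out = np.empty(nn)
    out[order] = ranked
    q[ok] = out
    return q
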