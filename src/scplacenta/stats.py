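"""Shared statistical primitives: BH step-up FDR and a vectorized
tie-corrected Wilcoxon rank-sum test.

The rank-sum test is vectorized over genes so that one-vs-rest marker
detection stays fast on thousands of genes; ``scipy.stats.mannwhitneyu``
serves as the reference implementation in the test suite. For very small
samples (total n below ``EXACT_MAX_N``) without ties the exact null
enumeration is used instead of the normal approximation.
"""

from __future__ import annotations

import numpy as np
import scipy.stats

EXACT_MAX_N = 25


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    Missing p-values (NaN) are propagated: they do not count toward the
    family size m and come back as NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if pv.size == 0:
        return out
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    qv = np.empty(m)
    qv[order] = q
    out[mask] = qv
    return out


def rank_sum_test(x: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-values, one per column of ``x``.

    Parameters
    ----------
    x : (n_obs, n_vars) array of values.
    in_group : boolean (n_obs,) mask of the first group.

    Uses the tie-corrected normal approximation with continuity
    correction; exact enumeration (via scipy) when total n < 25 and the
    column has no ties.
    """
    x = np.asarray(x, dtype=float)
    in_group = np.asarray(in_group, dtype=bool)
    n1 = int(in_group.sum())
    n2 = int((~in_group).sum())
    n = n1 + n2
    if x.ndim == 1:
        x = x[:, None]
    if n1 == 0 or n2 == 0:
        return np.full(x.shape[1], np.nan)

    ranks = scipy.stats.rankdata(x, axis=0)
    r1 = ranks[in_group].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0

    # tie correction term sum(t^3 - t) per column
    xs = np.sort(x, axis=0)
    same = np.vstack([np.zeros((1, x.shape[1]), bool), xs[1:] == xs[:-1]])
    tie_term = np.zeros(x.shape[1])
    has_ties = same.any(axis=0)
    for j in np.where(has_ties)[0]:
        _, counts = np.unique(xs[:, j], return_counts=True)
        tie_term[j] = np.sum(counts.astype(float) ** 3 - counts)

    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
    z = np.maximum(z, 0.0)
    p = 2.0 * scipy.stats.norm.sf(z)
    p = np.where(sigma2 <= 0, 1.0, np.minimum(p, 1.0))

    if n < EXACT_MAX_N:
        for j in np.where(~has_ties)[0]:
            res = scipy.stats.mannwhitneyu(
                x[in_group, j], x[~in_group, j], alternative="two-sided", method="exact")
            p[j] = res.pvalue
    return p


def pooled_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-tailed equal-variance (pooled) two-sample t-test."""
    res = scipy.stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)
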