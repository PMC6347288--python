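"""Shared statistical primitives.

The Wilcoxon rank-sum machinery here is deliberately hand-rolled and
vectorized: the enrichment procedures evaluate the same two-sample test for
every (component, metabolite set) or (permutation, metabolite set) pair, so
the rank transform is computed once per column and group sums are obtained
by matrix products.  The normal approximation uses average ranks for ties,
the tie-corrected variance, and a 0.5 continuity correction; the sign of z
is positive when the "in-group" values are larger.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["ranksum_z", "ranksum_z_matrix", "ols_association"]

# below this pooled sample size the exact rank-sum null is enumerated
# (scipy's exact Mann-Whitney path); above it the tie- and
# continuity-corrected normal approximation is used
EXACT_RANKSUM_N = 20


def _rank_and_ties(values: np.ndarray):
    """Column-wise average ranks (1-based) and tie-correction term sum(t^3-t)."""
    ranks = stats.rankdata(values, axis=0)
    tie_term = np.zeros(values.shape[1])
    for j in range(values.shape[1]):
        _, counts = np.unique(values[:, j], return_counts=True)
        t = counts[counts > 1].astype(float)
        tie_term[j] = np.sum(t**3 - t)
    return ranks, tie_term


def _z_from_ranksum(w, n1, n, tie_term):
    """Signed z for rank-sum W of a group of size n1 out of n observations."""
    n2 = n - n1
    mu = n1 * (n + 1) / 2.0
    var = (n1 * n2 / 12.0) * ((n + 1) - tie_term / (n * (n - 1.0)))
    var = np.maximum(var, 0.0)
    diff = w - mu
    corr = np.where(diff > 0, -0.5, np.where(diff < 0, 0.5, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (diff + corr) / np.sqrt(var), 0.0)
    return z


def ranksum_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-tailed Wilcoxon rank-sum test of `x` (in-group) vs `y`.

    Returns (z, p) with z > 0 when x tends to be larger.  Normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])[:, None]
    ranks, tie_term = _rank_and_ties(pooled)
    w = ranks[: len(x), 0].sum()
    z = float(_z_from_ranksum(w, len(x), len(pooled), tie_term[0]))
    if len(pooled) <= EXACT_RANKSUM_N:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    return z, min(p, 1.0)


def ranksum_z_matrix(values: np.ndarray, membership: np.ndarray):
    """Vectorized rank-sum tests for many columns against many groups.

    Parameters
    ----------
    values : (n, m) array
        Each column is one variable measured on the same n observations.
    membership : (n, s) boolean array
        Column k marks the in-group observations of group k.

    Returns
    -------
    z, p : (m, s) arrays
        Signed z and two-tailed p for testing, per (variable, group), whether
        in-group values exceed out-group values.
    """
    values = np.asarray(values, dtype=float)
    membership = np.asarray(membership, dtype=bool)
    n, m = values.shape
    ranks, tie_term = _rank_and_ties(values)
    n1 = membership.sum(axis=0).astype(float)  # (s,)
    w = ranks.T @ membership  # (m, s)
    z = _z_from_ranksum(w, n1[None, :], n, tie_term[:, None])
    if n <= EXACT_RANKSUM_N:
        p = np.ones_like(z)
        for j in range(membership.shape[1]):
            mask = membership[:, j]
            if not mask.any() or mask.all():
                continue
            for i in range(values.shape[1]):
                p[i, j] = stats.mannwhitneyu(
                    values[mask, i], values[~mask, i], alternative="two-sided"
                ).pvalue
    else:
        p = np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0)
    return z, p


def ols_association(y: np.ndarray, X: np.ndarray):
    """Simple linear regression of y on each column of X (with intercept).

    Returns (beta, se, p) arrays, one entry per column; two-sided t test on
    n - 2 degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations for per-signal regression")
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sxx = np.sum(Xc**2, axis=0)
    sxy = Xc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / sxx, 0.0)
    resid_ss = np.sum(yc**2) - beta * sxy
    dof = n - 2
    sigma2 = np.maximum(resid_ss, 0.0) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(sxx > 0, sigma2 / sxx, np.inf))
    tstat = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return beta, se, np.clip(p, np.nextafter(0, 1), 1.0)
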