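"""Shared statistical primitives used by more than one analysis module.

These are thin, policy-carrying wrappers around scipy/statsmodels routines:
the policies (exact vs. asymptotic switch-over, tie handling, degenerate-input
conventions) are fixed here so every module applies the same rules.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Combined sample size at or below which rank tests use the exact null
#: distribution (no ties permitting); above it, the tie-corrected normal
#: approximation is used.
EXACT_RANKTEST_MAX_N = 20


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t statistic, Welch-Satterthwaite df and two-sided p.

    Convention for degenerate inputs: if both groups have zero variance the
    statistic is 0 and p is 1 when the means are equal; if the means differ
    the statistic is signed infinity and p is 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, float(na + nb - 2), 1.0
        return float(np.sign(diff) * np.inf), float(na + nb - 2), 0.0
    t = diff / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when the combined sample size is at most
    ``EXACT_RANKTEST_MAX_N`` and the data are tie-free; otherwise the normal
    approximation with tie correction and continuity correction.

    Returns ``(U, p)`` where U counts pairs in which an observation from ``a``
    exceeds one from ``b`` (scipy convention).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("Mann-Whitney requires at least one observation per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # complete tie: no rank information, U at its null mean
        return float(len(a) * len(b) / 2.0), 1.0
    tie_free = len(np.unique(pooled)) == len(pooled)
    if len(pooled) <= EXACT_RANKTEST_MAX_N and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    rho = stats.spearmanr(x, y).statistic
    return float(rho)
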