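"""Independent brute-force reference implementations used only by tests.

Each function recomputes a statistic from its textbook definition —
enumeration over arrangements for rank tests, explicit step-up for BH,
rank-then-Pearson for Spearman — deliberately sharing no code with the
package implementations they check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def welch_t_oracle(a, b):
    """Textbook Welch t, Welch-Satterthwaite df and two-sided p (via mpmath-free
    scipy.special for the t CDF only)."""
    from scipy.special import stdtr

    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * (1.0 - stdtr(df, abs(t)))
    return t, df, p


def mann_whitney_exact_oracle(a, b):
    """Exact two-sided Mann-Whitney by full enumeration over all
    C(n1+n2, n1) assignments of the pooled values to group a.

    Two-sided p = 2 * min(P(U <= u_obs), P(U >= u_obs)), capped at 1 — the
    convention matching the symmetric exact null.  Requires tie-free data.
    """
    a, b = list(map(float, a)), list(map(float, b))
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1 = len(a)

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = u_stat(a, b)
    us = []
    for idx in combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(ga, gb))
    us = np.array(us)
    n_total = len(us)
    p = 2.0 * min((us <= u_obs).sum(), (us >= u_obs).sum()) / n_total
    return u_obs, min(p, 1.0)


def bh_oracle(pvalues):
    """Benjamini-Hochberg step-up by explicit sorting and cumulative min."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        value = min(prev, p[i] * m / rank_from_end)
        q[i] = value
        prev = value
    return q


def spearman_oracle(x, y):
    """Spearman rho as Pearson correlation of average-tie ranks, with the
    ranking done by hand."""

    def average_ranks(values):
        values = list(map(float, values))
        order = sorted(range(len(values)), key=lambda i: values[i])
        ranks = [0.0] * len(values)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = average_ranks(x), average_ranks(y)
    rx, ry = np.asarray(rx), np.asarray(ry)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def ks_uniform_oracle(values):
    """One-sample KS statistics against Uniform(0,1) by direct ECDF
    enumeration at every sample point (both one-sided sups and the
    two-sided max)."""
    u = sorted(map(float, values))
    n = len(u)
    d_plus = max((i + 1) / n - u[i] for i in range(n))
    d_minus = max(u[i] - i / n for i in range(n))
    return d_plus, d_minus, max(d_plus, d_minus)


def rank_sum_enrichment_oracle(gene_fc: dict, term_genes) -> float:
    """Exact two-sided rank-sum enrichment p for one term by enumerating all
    placements of |term| genes among the input list."""
    genes = list(gene_fc)
    in_term = [g for g in genes if g in set(term_genes)]
    fc = {g: gene_fc[g] for g in genes}
    a = [fc[g] for g in in_term]
    b = [fc[g] for g in genes if g not in set(term_genes)]
    _, p = mann_whitney_exact_oracle(a, b)
    return p
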