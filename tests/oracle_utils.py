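"""Independent brute-force oracles used to check the statistical machinery.

These deliberately recompute everything from first principles (full
enumeration, direct ECDFs, hypergeometric sums) without touching the
implementations under test.
"""
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import hypergeom


def ecdf_sup_diff(a, b):
    """sup_x (F_a(x) - F_b(x)) by direct ECDF evaluation."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    xs = np.concatenate([a, b])
    best = -np.inf
    for x in xs:
        fa = (a <= x).mean()
        fb = (b <= x).mean()
        best = max(best, fa - fb)
    return best


def ks_one_sided_exact_p(a, b):
    """Exact one-sided KS p by enumerating all group assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    na = a.size
    d_obs = ecdf_sup_diff(a, b)
    idx_all = set(range(pooled.size))
    hits = total = 0
    for ia in combinations(range(pooled.size), na):
        pa = pooled[list(ia)]
        pb = pooled[sorted(idx_all - set(ia))]
        total += 1
        if ecdf_sup_diff(pa, pb) >= d_obs - 1e-12:
            hits += 1
    return hits / total


def rank_sum_exact_p(a, b, alternative="two-sided"):
    """Exact rank-sum p by enumerating assignments of the pooled ranks."""
    from scipy.stats import rankdata

    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    na = a.size
    w_obs = ranks[:na].sum()
    n_le = n_ge = total = 0
    for ia in combinations(range(pooled.size), na):
        w = ranks[list(ia)].sum()
        total += 1
        if w <= w_obs + 1e-9:
            n_le += 1
        if w >= w_obs - 1e-9:
            n_ge += 1
    p_le, p_ge = n_le / total, n_ge / total
    if alternative == "less":
        return p_le
    if alternative == "greater":
        return p_ge
    return min(1.0, 2.0 * min(p_le, p_ge))


def fisher_two_sided_p(table):
    """Two-sided Fisher p by summing hypergeometric probabilities of all
    tables with the observed margins that are at most as probable."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    rv = hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        px = rv.pmf(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(1.0, total)


def brute_force_quantile(values, q):
    """Sort-based quantile with linear interpolation."""
    v = np.sort(np.asarray(values, float))
    pos = q * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac
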