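"""Statistical tests: rank-sum differential expression, Fisher exact
lineage-specificity, pairwise gene correlation, condition-shift tests and
cross-level coherence.

The Wilcoxon rank-sum test is implemented directly so that its exact
small-sample path (full enumeration of group assignments, valid under
ties) and its tie-corrected normal approximation are explicit; the same
implementation backs differential expression and the one-sided wild-type
versus knockout shift tests.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .preprocess import NormalizedMatrix

_EXACT_MAX_GROUP = 10
_EXACT_MAX_TOTAL = 30


def fisher_exact_table(table: np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    Single shared implementation behind gene-set enrichment and the
    lineage-specificity contrast.
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(table < 0):
        raise ValueError("table entries must be non-negative")
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Rank-sum test of two samples; returns (W of sample a, p).

    ``alternative='less'`` tests a shifted below b, ``'greater'`` the
    opposite. Exact by enumeration of group assignments when the smaller
    group has <= 8 observations (correct under ties); otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:na].sum())

    if min(na, nb) <= _EXACT_MAX_GROUP and na + nb <= _EXACT_MAX_TOTAL:
        p_le, p_ge = _exact_rank_sum_tails(ranks, na, w)
        if alternative == "less":
            p = p_le
        elif alternative == "greater":
            p = p_ge
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return w, float(p)

    n = na + nb
    mu = na * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return w, 1.0
    sd = np.sqrt(var)
    if alternative == "less":
        p = sps.norm.cdf((w - mu + 0.5) / sd)
    elif alternative == "greater":
        p = sps.norm.sf((w - mu - 0.5) / sd)
    else:
        z = (abs(w - mu) - 0.5) / sd
        p = 2.0 * sps.norm.sf(max(z, 0.0))
    return w, float(min(1.0, p))


def _exact_rank_sum_tails(
    ranks: np.ndarray, na: int, w: float
) -> tuple[float, float]:
    """Exact permutation tails P(W <= w) and P(W >= w) of the rank sum.

    Counts the size-na subsets of the observed (mid)ranks by a subset-sum
    dynamic programme; doubling the midranks makes every value an integer,
    so ties are handled exactly. Equivalent to full enumeration of all
    C(n, na) group assignments.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total_sum = int(r2.sum())
    # counts[k][s] = number of k-subsets of the processed ranks summing to s
    counts = np.zeros((na + 1, total_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in r2:  # doubled midranks are integers >= 2
        for k in range(na, 0, -1):
            counts[k, r:] += counts[k - 1, : total_sum + 1 - r]
    dist = counts[na]
    n_total = comb(len(ranks), na)
    w2 = 2 * w
    sums = np.arange(total_sum + 1)
    p_le = dist[sums <= w2 + 1e-9].sum() / n_total
    p_ge = dist[sums >= w2 - 1e-9].sum() / n_total
    return float(p_le), float(p_ge)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]


def wilcoxon_de(
    nm: NormalizedMatrix,
    group_a: np.ndarray,
    group_b: np.ndarray,
) -> pd.DataFrame:
    """Per-gene two-sided rank-sum differential expression, A versus B.

    No fold-change pre-filter is applied: every gene is tested and BH-
    adjusted across all tested genes. log2FC is the log2 ratio of
    (mean(expm1(values)) + 1) between groups on the normalised scale;
    pct_a/pct_b are the detection fractions per group.
    """
    ia = _as_indices(group_a, nm.n_cells)
    ib = _as_indices(group_b, nm.n_cells)
    if set(ia) & set(ib):
        raise ValueError("groups overlap; differential expression needs disjoint groups")
    if len(ia) < 3 or len(ib) < 3:
        raise ValueError("both groups need at least 3 cells")
    va = nm.values[ia]
    vb = nm.values[ib]
    mean_a = np.expm1(va).mean(axis=0)
    mean_b = np.expm1(vb).mean(axis=0)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    pvals = np.empty(nm.values.shape[1])
    for j in range(nm.values.shape[1]):
        _, pvals[j] = wilcoxon_rank_sum(va[:, j], vb[:, j], "two-sided")
    out = pd.DataFrame(
        {
            "log2_fold_change": log2fc,
            "p_value": pvals,
            "adjusted_p": bh_adjust(pvals),
            "pct_a": (va > 0).mean(axis=0),
            "pct_b": (vb > 0).mean(axis=0),
        },
        index=list(nm.gene_ids),
    )
    return out


def _as_indices(group: np.ndarray, n: int) -> np.ndarray:
    group = np.asarray(group)
    if group.dtype == bool:
        if group.size != n:
            raise ValueError("boolean group mask has wrong length")
        return np.flatnonzero(group)
    return group.astype(int)


def lineage_specificity_test(
    expressing_a: int, total_a: int, expressing_b: int, total_b: int
) -> tuple[float, float]:
    """Two-sided Fisher exact contrast of expressing fractions; (p, OR).

    Used for lineage-specificity statements such as comparing Runx3
    detection in CD4-lineage cells against Zbtb7b detection in CD8-lineage
    cells.
    """
    for name, (e, t) in {
        "a": (expressing_a, total_a),
        "b": (expressing_b, total_b),
    }.items():
        if e < 0 or t < 0 or e > t:
            raise ValueError(
                f"group {name}: expressing count {e} inconsistent with total {t}"
            )
    table = np.array(
        [
            [expressing_a, total_a - expressing_a],
            [expressing_b, total_b - expressing_b],
        ]
    )
    odds, p = fisher_exact_table(table)
    return p, odds


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    constant: bool = False


def pairwise_gene_correlation(
    nm: NormalizedMatrix,
    gene1: str,
    gene2: str,
    cells: np.ndarray | None = None,
) -> CorrelationResult:
    """Pearson correlation of two genes across cells, with t-test p-value.

    A constant gene makes the correlation undefined; the result is flagged
    rather than raised.
    """
    x = nm.gene_values(gene1)
    y = nm.gene_values(gene2)
    if cells is not None:
        idx = _as_indices(cells, nm.n_cells)
        x, y = x[idx], y[idx]
    if x.size < 3:
        raise ValueError("need at least 3 cells for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), int(x.size), constant=True)
    res = sps.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))


def condition_shift_test(
    nm_wt: NormalizedMatrix,
    nm_ko: NormalizedMatrix,
    state_mask_wt: np.ndarray,
    state_mask_ko: np.ndarray,
    gene: str,
) -> float:
    """One-sided rank-sum p-value that a gene is lower in KO than WT cells
    of a given coreceptor state."""
    iw = _as_indices(state_mask_wt, nm_wt.n_cells)
    ik = _as_indices(state_mask_ko, nm_ko.n_cells)
    if len(iw) < 3 or len(ik) < 3:
        raise ValueError("both conditions need at least 3 cells in the state")
    wt_vals = nm_wt.gene_values(gene)[iw]
    ko_vals = nm_ko.gene_values(gene)[ik]
    _, p = wilcoxon_rank_sum(ko_vals, wt_vals, alternative="less")
    return p


def linear_by_linear_test(table: np.ndarray) -> tuple[float, float]:
    """Asymptotic linear-by-linear association test on an ordered r x c table.

    Integer scores 0..r-1 / 0..c-1; the statistic is M^2 = (N - 1) r^2 with
    r the score correlation, referred to chi-square with 1 df.
    """
    t = np.asarray(table, dtype=float)
    n = t.sum()
    if n < 2:
        raise ValueError("table needs at least 2 observations")
    u = np.arange(t.shape[0], dtype=float)
    v = np.arange(t.shape[1], dtype=float)
    pu = t.sum(axis=1) / n
    pv = t.sum(axis=0) / n
    mu_u = (u * pu).sum()
    mu_v = (v * pv).sum()
    sd_u = np.sqrt(((u - mu_u) ** 2 * pu).sum())
    sd_v = np.sqrt(((v - mu_v) ** 2 * pv).sum())
    if sd_u == 0 or sd_v == 0:
        return 0.0, 1.0
    cov = ((u[:, None] - mu_u) * (v[None, :] - mu_v) * t / n).sum()
    r = cov / (sd_u * sd_v)
    m2 = (n - 1) * r**2
    return float(m2), float(sps.chi2.sf(m2, 1))


def cross_level_coherence(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    fc_threshold: float = 0.25,
) -> tuple[float, float]:
    """Coherence between two differential-expression comparisons.

    Returns the Pearson correlation of the shared genes' log2 fold changes
    and the p-value of a linear-by-linear association test on the 3x3
    table of regulation direction (down / flat / up at ``fc_threshold``).
    """
    shared = de_a.index.intersection(de_b.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes; need at least 10")
    fa = de_a.loc[shared, "log2_fold_change"].to_numpy()
    fb = de_b.loc[shared, "log2_fold_change"].to_numpy()
    r = float(np.corrcoef(fa, fb)[0, 1])

    def discretize(f: np.ndarray) -> np.ndarray:
        return np.digitize(f, [-fc_threshold, fc_threshold])  # 0 down, 1 flat, 2 up

    da, db = discretize(fa), discretize(fb)
    table = np.zeros((3, 3))
    for i, j in zip(da, db):
        table[i, j] += 1
    _, p = linear_by_linear_test(table)
    return r, p
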