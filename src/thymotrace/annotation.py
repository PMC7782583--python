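"""Attaching biological meaning to principal components.

Each PC is characterised by (i) per-gene Pearson correlation between
expression and the PC score, (ii) a spline-based test of the null of no
change along the axis, and (iii) Fisher exact enrichment of the top axis
genes against reference gene sets (activation and lineage markers derived
from population RNA-seq, or the generator's truth sets on synthetic data).
The PC is labelled with the most significantly enriched set.

Top axis genes can be ranked by absolute correlation (``abs_r``) or by the
spline-test p-value (``spline_p``, the default).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .embedding import Embedding
from .preprocess import NormalizedMatrix
from .stats import fisher_exact_table
from .types import GeneSetRef


@dataclass
class EnrichmentResult:
    odds_ratio: float
    p_value: float
    table: np.ndarray  # 2x2: [[sel&ref, sel&~ref], [~sel&ref, ~sel&~ref]]


@dataclass
class AxisAnnotation:
    pc: int
    top_genes: list[str]
    enrichments: dict[str, EnrichmentResult]
    label: str


def gene_axis_correlation(
    nm: NormalizedMatrix, emb: Embedding, pc: int
) -> pd.DataFrame:
    """Pearson R of every gene's expression with a PC score.

    Constant genes get R = 0 and are flagged.
    """
    s = emb.pc(pc)
    x = nm.values
    xc = x - x.mean(axis=0)
    sc = s - s.mean()
    sd_x = x.std(axis=0)
    sd_s = s.std()
    constant = sd_x == 0
    denom = sd_x * sd_s * x.shape[0]
    denom[constant] = 1.0
    r = (xc * sc[:, None]).sum(axis=0) / denom
    r[constant] = 0.0
    if sd_s == 0:
        raise ValueError(f"PC{pc} scores are constant")
    return pd.DataFrame(
        {"r": r, "constant": constant}, index=list(nm.gene_ids)
    )


def top_correlated(rs: pd.Series, n: int = 1000) -> list[str]:
    """Top-n genes by |R|; ties broken by lexical gene id."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(rs):
        warnings.warn(
            f"requested top {n} of {len(rs)} genes; returning all", stacklevel=2
        )
        n = len(rs)
    order = sorted(rs.index, key=lambda g: (-abs(rs[g]), g))
    return order[:n]


def fisher_enrichment(
    selected: Sequence[str], ref: GeneSetRef, background: Sequence[str]
) -> EnrichmentResult:
    """Two-sided Fisher exact test of selected-gene membership in a set."""
    bg = set(background)
    sel = set(selected)
    if not sel <= bg:
        raise ValueError("selected genes must be a subset of the background")
    ref_in_bg = ref.genes & bg
    if not ref_in_bg:
        raise ValueError(
            f"reference set {ref.name!r} shares no genes with the background"
        )
    a = len(sel & ref_in_bg)
    b = len(sel) - a
    c = len(ref_in_bg) - a
    d = len(bg) - len(sel) - c
    table = np.array([[a, b], [c, d]])
    odds, p = fisher_exact_table(table)
    return EnrichmentResult(odds, p, table)


# ---------------------------------------------------------------------------
# spline change-along-axis test


def _natural_spline_basis(x: np.ndarray, df: int) -> np.ndarray:
    """Natural cubic spline basis with ``df`` degrees of freedom.

    Knots at equally spaced quantiles of x (df + 1 knots); columns are the
    linear term plus df - 1 natural truncated-power terms. The intercept is
    not included.
    """
    x = np.asarray(x, dtype=float)
    k = df + 1
    knots = np.quantile(x, np.linspace(0, 1, k))
    knots = np.unique(knots)
    if len(knots) < 2:
        raise ValueError("axis is (nearly) constant; spline basis undefined")
    kk = len(knots)

    def d(j: int) -> np.ndarray:
        num = np.maximum(x - knots[j], 0) ** 3 - np.maximum(x - knots[-1], 0) ** 3
        return num / (knots[-1] - knots[j])

    cols = [x]
    d_last = d(kk - 2)
    for j in range(kk - 2):
        cols.append(d(j) - d_last)
    return np.column_stack(cols)


def spline_change_test(
    expr: np.ndarray, axis: np.ndarray, df: int = 4
) -> tuple[float, float]:
    """F-test of a natural-spline fit of expression on an axis vs intercept."""
    f, p = change_along_axis(np.asarray(expr, float)[:, None], axis, df=df)
    return float(f[0]), float(p[0])


def change_along_axis(
    exprs: np.ndarray, axis: np.ndarray, df: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised spline change test over gene columns.

    Returns per-gene (F, p). Constant genes get F = 0, p = 1.
    """
    axis = np.asarray(axis, dtype=float)
    y = np.asarray(exprs, dtype=float)
    n = len(axis)
    if np.std(axis) == 0:
        raise ValueError("axis is constant; no change can be tested")
    basis = _natural_spline_basis(axis, df)
    p_model = basis.shape[1]
    if n < p_model + 2:
        raise ValueError(f"need at least df + 2 = {p_model + 2} cells, got {n}")
    design = np.column_stack([np.ones(n), basis])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss1 = (resid**2).sum(axis=0)
    rss0 = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    df_den = n - design.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss1) / p_model) / (rss1 / df_den)
    f = np.where(rss0 <= 0, 0.0, f)
    f = np.clip(f, 0.0, None)
    p = sps.f.sf(f, p_model, df_den)
    p = np.where(rss0 <= 0, 1.0, p)
    return f, p


def top_genes_along_axis(
    nm: NormalizedMatrix,
    emb: Embedding,
    pc: int,
    n: int = 1000,
    rank_by: str = "spline_p",
    df: int = 4,
) -> list[str]:
    """Genes most associated with a PC, by |R| or by spline-test p-value."""
    if rank_by == "abs_r":
        rs = gene_axis_correlation(nm, emb, pc)["r"]
        return top_correlated(rs, n)
    if rank_by == "spline_p":
        _, p = change_along_axis(nm.values, emb.pc(pc), df=df)
        ps = pd.Series(p, index=list(nm.gene_ids))
        if n > len(ps):
            warnings.warn(
                f"requested top {n} of {len(ps)} genes; returning all", stacklevel=2
            )
            n = len(ps)
        order = sorted(ps.index, key=lambda g: (ps[g], g))
        return order[:n]
    raise ValueError("rank_by must be 'abs_r' or 'spline_p'")


def label_axes(
    enrichments: Mapping[int, Mapping[str, EnrichmentResult]],
    alpha: float = 0.01,
) -> dict[int, str]:
    """Label each PC with its most significantly enriched gene set.

    PCs where no set passes ``alpha`` are labelled 'unassigned'.
    """
    labels = {}
    for pc, res in enrichments.items():
        best = min(res, key=lambda name: (res[name].p_value, name), default=None)
        if best is None or res[best].p_value >= alpha:
            labels[pc] = "unassigned"
        else:
            labels[pc] = best
    return labels


def annotate_axes(
    nm: NormalizedMatrix,
    emb: Embedding,
    genesets: Mapping[str, GeneSetRef],
    pcs: Sequence[int] = (1, 2, 3),
    n_top: int = 1000,
    rank_by: str = "spline_p",
    df: int = 4,
    alpha: float = 0.01,
) -> dict[int, AxisAnnotation]:
    """Full per-PC annotation: top genes, enrichments, label."""
    per_pc_enrich: dict[int, dict[str, EnrichmentResult]] = {}
    per_pc_top: dict[int, list[str]] = {}
    background = list(nm.gene_ids)
    for pc in pcs:
        top = top_genes_along_axis(nm, emb, pc, n=n_top, rank_by=rank_by, df=df)
        per_pc_top[pc] = top
        per_pc_enrich[pc] = {
            name: fisher_enrichment(top, gs, background)
            for name, gs in genesets.items()
        }
    labels = label_axes(per_pc_enrich, alpha=alpha)
    return {
        pc: AxisAnnotation(pc, per_pc_top[pc], per_pc_enrich[pc], labels[pc])
        for pc in pcs
    }
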