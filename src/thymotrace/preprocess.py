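"""QC filtering, log-normalisation and highly-variable-gene selection.

Cells are kept inside a total-read-count window (deep SMART-seq libraries;
default bounds 500,000-1,500,000 reads). Expression is log-normalised as
``log(1 + count * scale_factor / cell_total)``. Highly variable genes are
scored by a variance-stabilising scheme: a lowess trend of log10 variance on
log10 mean predicts each gene's expected variance, counts are standardised
by the trend and clipped at sqrt(n_cells), and the score is the variance of
the clipped standardised values. State-defining genes (Cd4, Cd8a, Cd8b1)
are excluded after scoring so the embedding does not simply encode the
coreceptor states it is later used to order.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .types import CountMatrix

log = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """Log-scale normalised expression (cells x genes, all values >= 0)."""

    values: np.ndarray
    cell_ids: Sequence[str]
    gene_ids: Sequence[str]
    scale_factor: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = list(self.cell_ids)
        self.gene_ids = list(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present") from None

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[:, self.gene_index(gene)]

    def subset_cells(self, mask: np.ndarray) -> "NormalizedMatrix":
        idx = np.flatnonzero(mask) if np.asarray(mask).dtype == bool else np.asarray(mask)
        return NormalizedMatrix(
            self.values[idx],
            [self.cell_ids[i] for i in idx],
            list(self.gene_ids),
            self.scale_factor,
        )


@dataclass
class HVGSet:
    """Highly variable genes, ordered by descending standardised variance."""

    genes: list[str]
    score: pd.Series  # standardised variance per scored gene

    def __len__(self) -> int:
        return len(self.genes)


def qc_filter_cells(
    cm: CountMatrix, min_total: int = 500_000, max_total: int = 1_500_000
) -> CountMatrix:
    """Keep cells whose total counts lie in [min_total, max_total]."""
    if not min_total < max_total:
        raise ValueError("min_total must be smaller than max_total")
    totals = cm.totals()
    keep = (totals >= min_total) & (totals <= max_total)
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError(
            f"QC bounds [{min_total}, {max_total}] removed all {cm.n_cells} cells"
        )
    log.info("qc_filter_cells removed %d of %d cells", n_removed, cm.n_cells)
    return cm.subset_cells(keep)


def lognormalize(cm: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """Depth-normalise and log-transform: log(1 + count * sf / total)."""
    totals = cm.totals().astype(float)
    if np.any(totals == 0):
        raise ValueError(
            "cells with zero total counts present; run qc_filter_cells first"
        )
    values = np.log1p(cm.counts * (scale_factor / totals[:, None]))
    return NormalizedMatrix(values, list(cm.cell_ids), list(cm.gene_ids), scale_factor)


def hvg_scores(cm: CountMatrix, lowess_frac: float = 0.3) -> pd.Series:
    """Standardised-variance score per gene (variance-stabilising scheme).

    Genes with zero mean or zero variance score 0. The mean-variance trend
    is fitted by lowess on log10 scales over the remaining genes.
    """
    counts = cm.counts.astype(float)
    n = counts.shape[0]
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    score = np.zeros(counts.shape[1])
    ok = (mean > 0) & (var > 0)
    if ok.sum() >= 2:
        lx = np.log10(mean[ok])
        ly = np.log10(var[ok])
        # keep at least ~10 genes in every lowess window so the local fit
        # is defined even on very small gene panels
        frac = max(lowess_frac, min(1.0, 10.0 / ok.sum()))
        with np.errstate(invalid="ignore", divide="ignore"):
            fitted = lowess(ly, lx, frac=frac, xvals=lx)
        bad = ~np.isfinite(fitted)
        if bad.any():
            fitted[bad] = ly.mean()
        sd_exp = np.sqrt(10.0**fitted)
        z = (counts[:, ok] - mean[ok][None, :]) / sd_exp[None, :]
        clip = np.sqrt(n)
        z = np.clip(z, -clip, clip)
        score[ok] = z.var(axis=0, ddof=1)
    return pd.Series(score, index=list(cm.gene_ids), name="standardized_variance")


def select_hvg(
    cm: CountMatrix,
    n_top: int = 2000,
    exclude: Iterable[str] = ("Cd4", "Cd8a", "Cd8b1"),
    lowess_frac: float = 0.3,
) -> HVGSet:
    """Top ``n_top`` genes by standardised variance, after dropping ``exclude``.

    Exclusion happens after scoring and before truncation, so n_top is
    honoured net of the excluded genes. Ties are broken by lexical gene id,
    making the selection deterministic.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    score = hvg_scores(cm, lowess_frac=lowess_frac)
    excluded = set(exclude)
    kept = score.drop(labels=[g for g in excluded if g in score.index])
    order = sorted(kept.index, key=lambda g: (-kept[g], g))
    if n_top > len(order):
        warnings.warn(
            f"requested {n_top} highly variable genes but only {len(order)} "
            "are available after exclusions; returning all",
            stacklevel=2,
        )
        n_top = len(order)
    genes = order[:n_top]
    return HVGSet(genes, kept.loc[genes])
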