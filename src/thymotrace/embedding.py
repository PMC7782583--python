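"""PCA embedding of the normalised data on highly variable genes.

The first three components carry the analysis: PC1 is progressive
maturation, PC2 transient activation, PC3 CD4/CD8 lineage identity. PCA is
sign-ambiguous, so axes are oriented by biology, not by loading-sign
heuristics: PC1 so that single-positive cells score above pre-selection DP,
PC2 so that activation-marker expression correlates positively with the
score, PC3 so that CD4 SP score above CD8 SP. Variance is reported both as
a fraction of total variance and as a fraction of the first five PCs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .preprocess import HVGSet, NormalizedMatrix
from .types import CellAnnotation

_SCALE_CLIP = 10.0  # bound on standardised values, limits outlier leverage


@dataclass
class Embedding:
    """PC scores/loadings with variance fractions and axis orientation."""

    scores: np.ndarray  # cells x k
    loadings: np.ndarray  # hvg genes x k
    hvg_genes: list[str]
    cell_ids: list[str]
    var_fraction_total: np.ndarray
    var_fraction_first5: np.ndarray
    orientation: dict[int, dict] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def pc(self, i: int) -> np.ndarray:
        """Scores of the i-th component (1-based)."""
        if not 1 <= i <= self.k:
            raise ValueError(f"PC{i} not available (k={self.k})")
        return self.scores[:, i - 1]

    def flip(self, i: int, rationale: str) -> "Embedding":
        scores = self.scores.copy()
        loadings = self.loadings.copy()
        scores[:, i - 1] *= -1
        loadings[:, i - 1] *= -1
        orientation = dict(self.orientation)
        orientation[i] = {"sign": -1, "rationale": rationale}
        return replace(self, scores=scores, loadings=loadings, orientation=orientation)


def pca(nm: NormalizedMatrix, hvg: HVGSet, k: int = 10) -> Embedding:
    """Centre/scale the HVG submatrix (clipped at +/-10 SD) and decompose.

    Deterministic up to the per-PC sign, which is fixed by making the
    largest-magnitude loading of each component positive; downstream
    orientation (orient_axes) then sets the biological direction.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    idx = [nm.gene_index(g) for g in hvg.genes]
    x = nm.values[:, idx]
    if k > min(x.shape):
        raise ValueError(f"k={k} exceeds min(n_cells, n_hvg)={min(x.shape)}")
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = np.clip((x - mu) / sd, -_SCALE_CLIP, _SCALE_CLIP)
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(z)
    loadings = model.components_.T
    # deterministic sign baseline
    for j in range(k):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    ev = model.explained_variance_
    total_var = z.var(axis=0, ddof=1).sum()
    var_total = ev / total_var
    n5 = min(5, k)
    var_first5 = ev[:n5] / ev[:n5].sum()
    return Embedding(
        scores=scores,
        loadings=loadings,
        hvg_genes=list(hvg.genes),
        cell_ids=list(nm.cell_ids),
        var_fraction_total=var_total,
        var_fraction_first5=var_first5,
    )


def orient_axes(
    emb: Embedding,
    ann: CellAnnotation,
    nm: NormalizedMatrix,
    activation_genes: Iterable[str],
) -> Embedding:
    """Fix the biological direction of PC1/PC2/PC3 (idempotent).

    PC1: maturation increases rightward (SP mean > CD69- DP mean).
    PC2: mean activation-marker expression correlates positively.
    PC3: CD4 SP mean above CD8 SP mean.
    Missing phenotype groups leave the axis unoriented with a warning.
    """
    if ann.cell_ids != emb.cell_ids:
        raise ValueError("annotation cells do not match embedding cells")
    pheno = ann.phenotype
    out = emb

    def group_mean(pc: int, groups: Sequence[str]) -> float | None:
        mask = np.isin(pheno, groups)
        if not mask.any():
            return None
        return float(out.pc(pc)[mask].mean())

    if out.k >= 1:
        sp = group_mean(1, ["CD4_SP", "CD8_SP"])
        dp = group_mean(1, ["CD69neg_DP"])
        if sp is None or dp is None:
            warnings.warn("PC1 left unoriented: SP or CD69- DP cells missing", stacklevel=2)
        else:
            if sp < dp:
                out = out.flip(1, "flipped so maturation (SP > CD69- DP) increases")
            out.orientation.setdefault(
                1, {"sign": 1, "rationale": "SP mean already above CD69- DP mean"}
            )
    if out.k >= 2:
        present = [g for g in activation_genes if g in nm.gene_ids]
        if not present:
            warnings.warn("PC2 left unoriented: no activation markers in matrix", stacklevel=2)
        else:
            marker = nm.values[:, [nm.gene_index(g) for g in present]].mean(axis=1)
            r = _safe_corr(out.pc(2), marker)
            if r is not None and r < 0:
                out = out.flip(2, "flipped so activation-marker expression correlates positively")
            out.orientation.setdefault(
                2, {"sign": 1, "rationale": "activation markers already correlate positively"}
            )
    if out.k >= 3:
        cd4 = group_mean(3, ["CD4_SP"])
        cd8 = group_mean(3, ["CD8_SP"])
        if cd4 is None or cd8 is None:
            warnings.warn("PC3 left unoriented: CD4 SP or CD8 SP cells missing", stacklevel=2)
        else:
            if cd4 < cd8:
                out = out.flip(3, "flipped so CD4 SP score above CD8 SP")
            out.orientation.setdefault(
                3, {"sign": 1, "rationale": "CD4 SP mean already above CD8 SP mean"}
            )
    return out


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float | None:
    if a.std() == 0 or b.std() == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def variance_report(emb: Embedding) -> pd.DataFrame:
    """Variance of PCs 1-5 as % of the first five PCs and % of total."""
    n = min(5, emb.k)
    if n < 5:
        warnings.warn(
            f"only {n} PCs available; reporting those (first-five normalisation "
            "uses the available PCs)",
            stacklevel=2,
        )
    rows = []
    for i in range(n):
        rows.append(
            {
                "pc": i + 1,
                "pct_of_first5": 100.0 * float(emb.var_fraction_first5[i]),
                "pct_of_total": 100.0 * float(emb.var_fraction_total[i]),
            }
        )
    return pd.DataFrame(rows).set_index("pc")
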