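"""Shared data model for the thymocyte lineage-choice analysis.

The substrate is a cells x genes integer count matrix from deep (SMART-seq
style) single-cell RNA-seq of sorted thymocyte subsets, annotated per cell
with the sort phenotype, the genetic condition (wild type or MHC class
II-deficient) and the batch. Gene identity is by case-sensitive symbol
(``Cd4``, ``Cd8a``, ``Cd8b1``).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Closed vocabulary of sort phenotypes, in developmental order.
PHENOTYPES = (
    "CD69neg_DP",
    "CD69pos_DP",
    "TCRbhi_DP",
    "CD4_CD8low",
    "CD4_SP",
    "CD8_SP",
)

#: Sort phenotypes pooled as selection intermediates.
INTERMEDIATE_PHENOTYPES = ("CD69pos_DP", "TCRbhi_DP", "CD4_CD8low")

CONDITIONS = ("WT", "MHCII_KO")


@dataclass
class CountMatrix:
    """Cells x genes non-negative integer counts with aligned identifiers."""

    counts: np.ndarray
    cell_ids: Sequence[str]
    gene_ids: Sequence[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D cells x genes array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.cell_ids = list(map(str, self.cell_ids))
        self.gene_ids = list(map(str, self.gene_ids))
        if len(self.cell_ids) != self.counts.shape[0]:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {self.counts.shape[0]} rows"
            )
        if len(self.gene_ids) != self.counts.shape[1]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {self.counts.shape[1]} columns"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids are not unique")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids are not unique")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present in the count matrix") from None

    def gene_counts(self, gene: str) -> np.ndarray:
        """Raw counts of one gene across cells."""
        return self.counts[:, self.gene_index(gene)]

    def totals(self) -> np.ndarray:
        """Total counts per cell."""
        return self.counts.sum(axis=1)

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            self.counts[idx],
            [self.cell_ids[i] for i in idx],
            list(self.gene_ids),
        )


@dataclass
class CellAnnotation:
    """Per-cell sort phenotype, condition and batch, one row per cell."""

    table: pd.DataFrame

    REQUIRED = ("cell_id", "phenotype", "condition", "batch")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"cell annotation is missing columns {missing}")
        if self.table["cell_id"].duplicated().any():
            raise ValueError("cell annotation has duplicated cell_id rows")
        bad = sorted(set(self.table["phenotype"]) - set(PHENOTYPES))
        if bad:
            raise ValueError(
                f"unknown phenotype labels {bad}; allowed vocabulary: {list(PHENOTYPES)}"
            )
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.table["cell_id"])

    @property
    def phenotype(self) -> np.ndarray:
        return self.table["phenotype"].to_numpy()

    @property
    def condition(self) -> np.ndarray:
        return self.table["condition"].to_numpy()

    def subset(self, mask: np.ndarray) -> "CellAnnotation":
        mask = np.asarray(mask)
        sub = self.table.loc[mask].reset_index(drop=True)
        return CellAnnotation(sub)

    def aligned_with(self, cm: CountMatrix) -> bool:
        return self.cell_ids == list(cm.cell_ids)


@dataclass(frozen=True)
class GeneSetRef:
    """A named reference gene set (e.g. activation or lineage markers)."""

    name: str
    genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def intersect(self, universe: Iterable[str]) -> frozenset:
        return self.genes & set(universe)
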