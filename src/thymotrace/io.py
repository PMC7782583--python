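"""Reading and writing the on-disk formats: Matrix Market counts with TSV
sidecars for cell and gene metadata, and plain-text gene sets.

Conventions: cells are MTX rows, genes are MTX columns (1-based indices per
the Matrix Market standard); sidecar TSVs carry a header row; cell order is
the MTX row order and is never silently changed. All outputs are UTF-8.
"""
from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .types import CellAnnotation, CountMatrix, GeneSetRef

log = logging.getLogger(__name__)


def write_counts(
    cm: CountMatrix,
    ann: Optional[CellAnnotation],
    mtx_path: str | Path,
    cells_tsv: str | Path,
    genes_tsv: str | Path,
    gene_meta: Optional[pd.DataFrame] = None,
) -> None:
    """Write counts as MTX plus cell/gene metadata TSVs."""
    mtx_path, cells_tsv, genes_tsv = Path(mtx_path), Path(cells_tsv), Path(genes_tsv)
    spio.mmwrite(str(mtx_path), sparse.coo_matrix(cm.counts.astype(np.int64)))
    if ann is not None:
        if not ann.aligned_with(cm):
            raise ValueError("annotation rows are not aligned with the count matrix")
        cells = ann.table
    else:
        cells = pd.DataFrame({"cell_id": cm.cell_ids})
    cells.to_csv(cells_tsv, sep="\t", index=False)
    if gene_meta is not None:
        genes = gene_meta
        if list(genes["gene_id"]) != list(cm.gene_ids):
            raise ValueError("gene metadata rows are not aligned with the count matrix")
    else:
        genes = pd.DataFrame({"gene_id": cm.gene_ids})
    genes.to_csv(genes_tsv, sep="\t", index=False)


def read_counts(
    mtx_path: str | Path, cells_tsv: str | Path, genes_tsv: str | Path
) -> tuple[CountMatrix, CellAnnotation]:
    """Read an MTX count matrix with its metadata sidecars.

    Rows are cells, columns are genes; metadata is aligned by row order.
    Raises on any dimension mismatch, naming the offending file.
    """
    mtx_path, cells_tsv, genes_tsv = Path(mtx_path), Path(cells_tsv), Path(genes_tsv)
    counts = np.asarray(spio.mmread(str(mtx_path)).todense()) if _is_sparse_file(
        mtx_path
    ) else np.asarray(spio.mmread(str(mtx_path)))
    cells = pd.read_csv(cells_tsv, sep="\t", dtype=str)
    genes = pd.read_csv(genes_tsv, sep="\t", dtype=str)
    if len(cells) != counts.shape[0]:
        raise ValueError(
            f"{cells_tsv} has {len(cells)} rows but {mtx_path} has "
            f"{counts.shape[0]} cell rows"
        )
    if len(genes) != counts.shape[1]:
        raise ValueError(
            f"{genes_tsv} has {len(genes)} rows but {mtx_path} has "
            f"{counts.shape[1]} gene columns"
        )
    cm = CountMatrix(
        counts.astype(np.int64), list(cells["cell_id"]), list(genes["gene_id"])
    )
    for col, default in (("condition", "WT"), ("batch", "B1")):
        if col not in cells.columns:
            cells[col] = default
    if "phenotype" not in cells.columns:
        raise ValueError(f"{cells_tsv} lacks a 'phenotype' column")
    ann = CellAnnotation(cells[["cell_id", "phenotype", "condition", "batch"]].copy())
    log.info("read %d cells x %d genes from %s", cm.n_cells, cm.n_genes, mtx_path)
    return cm, ann


def _is_sparse_file(path: Path) -> bool:
    with open(path) as fh:
        header = fh.readline()
    return "coordinate" in header


def read_gene_set(path: str | Path, name: Optional[str] = None) -> GeneSetRef:
    """Read a plain-text gene set, one symbol per line.

    Blank lines and duplicate symbols are dropped with a warning; an empty
    file is an error.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text(encoding="utf-8").splitlines()]
    symbols = [ln for ln in lines if ln]
    if not symbols:
        raise ValueError(f"gene set file {path} contains no gene symbols")
    unique = list(dict.fromkeys(symbols))
    n_dup = len(symbols) - len(unique)
    if n_dup:
        warnings.warn(
            f"gene set {path.name}: dropped {n_dup} duplicate symbol(s)",
            stacklevel=2,
        )
    return GeneSetRef(name or path.stem, frozenset(unique))


def write_gene_set(gs: GeneSetRef, path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(sorted(gs.genes)) + "\n", encoding="utf-8"
    )


def validate_dataset(cm: CountMatrix, ann: CellAnnotation) -> dict:
    """Structured summary of a dataset: composition and depth quantiles.

    Reports problems (misalignment, all-zero cells) without raising and
    never mutates its inputs.
    """
    report: dict = {"n_cells": cm.n_cells, "n_genes": cm.n_genes, "problems": []}
    if not ann.aligned_with(cm):
        report["problems"].append("annotation cell order differs from matrix order")
    comp = (
        ann.table.groupby(["phenotype", "condition"], observed=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    report["composition"] = comp.to_dict(orient="records")
    totals = cm.totals()
    qs = [0.0, 0.25, 0.5, 0.75, 1.0]
    report["total_counts_quantiles"] = {
        str(q): float(np.quantile(totals, q)) for q in qs
    }
    n_zero = int((totals == 0).sum())
    if n_zero:
        report["problems"].append(f"{n_zero} cell(s) with zero total counts")
    return report
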