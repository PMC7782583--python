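"""Per-cell coreceptor state calls from Cd4/Cd8a transcript detection.

At SMART-seq depth the coreceptor genes have very low dropout, so a cell's
raw-count detection of Cd4 and Cd8a (count >= tau, default tau = 1) gives a
four-way transcriptional state: Cd4+Cd8a+ (DP_state), Cd4+Cd8a-
(CD4_state), Cd4-Cd8a+ (CD8_state), Cd4-Cd8a- (DN_state). Detection
frequencies in sorted reference populations (pre-selection DP, CD4 SP,
CD8 SP) audit the dropout rate before the classifier is trusted on
selection intermediates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import CellAnnotation, CountMatrix, INTERMEDIATE_PHENOTYPES

STATES = ("DP_state", "CD4_state", "CD8_state", "DN_state")


@dataclass(frozen=True)
class CoreceptorCall:
    state: str
    cd4_count: int
    cd8a_count: int


def call_state(cd4: int, cd8a: int, tau: int = 1) -> CoreceptorCall:
    """Four-way state call from the two detection booleans."""
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if cd4 < 0 or cd8a < 0:
        raise ValueError("counts must be non-negative")
    cd4_pos = cd4 >= tau
    cd8a_pos = cd8a >= tau
    state = {
        (True, True): "DP_state",
        (True, False): "CD4_state",
        (False, True): "CD8_state",
        (False, False): "DN_state",
    }[(cd4_pos, cd8a_pos)]
    return CoreceptorCall(state, int(cd4), int(cd8a))


def call_states(cm: CountMatrix, tau: int = 1) -> pd.DataFrame:
    """Vectorised state call for every cell; index is cell_id."""
    if tau < 1:
        raise ValueError("tau must be >= 1")
    cd4 = cm.gene_counts("Cd4")
    cd8a = cm.gene_counts("Cd8a")
    cd4_pos = cd4 >= tau
    cd8a_pos = cd8a >= tau
    state = np.where(
        cd4_pos & cd8a_pos,
        "DP_state",
        np.where(cd4_pos, "CD4_state", np.where(cd8a_pos, "CD8_state", "DN_state")),
    )
    return pd.DataFrame(
        {"state": state, "cd4_count": cd4, "cd8a_count": cd8a},
        index=list(cm.cell_ids),
    )


def detection_frequencies(
    cm: CountMatrix,
    ann: CellAnnotation,
    genes: tuple[str, ...] = ("Cd4", "Cd8a"),
    tau: int = 1,
) -> pd.DataFrame:
    """Fraction of cells per phenotype with count >= tau for each gene.

    The dropout audit run before classification; raises if a gene is
    missing, naming it.
    """
    for g in genes:
        if g not in cm.gene_ids:
            raise KeyError(f"gene {g!r} not present in the count matrix")
    rows = {}
    pheno = ann.phenotype
    for p in pd.unique(pheno):
        mask = pheno == p
        rows[p] = {
            g: float((cm.gene_counts(g)[mask] >= tau).mean()) for g in genes
        }
    out = pd.DataFrame(rows).T
    out.index.name = "phenotype"
    return out


def pool_intermediates(ann: CellAnnotation) -> np.ndarray:
    """Boolean mask of the pooled selection intermediates
    (CD69+ DP, TCRbeta-hi DP, CD4+CD8low)."""
    return np.isin(ann.phenotype, INTERMEDIATE_PHENOTYPES)
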