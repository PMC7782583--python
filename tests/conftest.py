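import warnings

import numpy as np
import pytest

import thymotrace as tt
from thymotrace.coreceptor import call_states, pool_intermediates


@pytest.fixture(scope="session")
def wt_dataset():
    """Default sequential-timing wild-type dataset (300 cells x 500 genes)."""
    cfg = tt.SimulationConfig(seed=0)
    return tt.generate_dataset(cfg)


@pytest.fixture(scope="session")
def wt_products(wt_dataset):
    """Preprocessed products of the default wild-type dataset."""
    cm, ann, truth = wt_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cm_qc = tt.qc_filter_cells(cm)
        keep = np.isin(ann.table["cell_id"], cm_qc.cell_ids)
        ann_qc = ann.subset(keep)
        nm = tt.lognormalize(cm_qc)
        hvg = tt.select_hvg(cm_qc)
        emb = tt.pca(nm, hvg, k=10)
        emb = tt.orient_axes(
            emb, ann_qc, nm, truth.truth_genesets["activation"].genes
        )
    calls = call_states(cm_qc)
    inter = pool_intermediates(ann_qc)
    return {
        "cm": cm_qc,
        "ann": ann_qc,
        "truth": truth,
        "nm": nm,
        "hvg": hvg,
        "emb": emb,
        "calls": calls,
        "intermediates": inter,
    }
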