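import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from snanno.sim import generate_cohort, small_config


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-nucleus, 1200-gene simulated cohort with ground truth."""
    return generate_cohort(small_config(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_adata(counts, genes=None, barcodes=None, **obs_cols):
    """Small helper to build a counts AnnData from a dense array."""
    counts = np.asarray(counts)
    n, g = counts.shape
    genes = list(genes) if genes is not None else [f"g{i}" for i in range(g)]
    barcodes = (
        list(barcodes) if barcodes is not None else [f"bc{i}" for i in range(n)]
    )
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    for k, v in obs_cols.items():
        obs[k] = v
    return ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.int64)),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
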