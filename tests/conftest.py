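import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from eecfate import io_qc, synthetic


def make_adata(counts, gene_names=None, cell_names=None, batch=None) -> AnnData:
    """Raw-count AnnData toy with gene flags annotated."""
    counts = np.asarray(counts, dtype=np.float64)
    n, g = counts.shape
    gene_names = gene_names or [f"g{i}" for i in range(g)]
    cell_names = cell_names or [f"c{i}" for i in range(n)]
    adata = AnnData(
        X=counts,
        obs=pd.DataFrame(index=pd.Index(cell_names, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(gene_names, name="gene_id")),
    )
    if batch is not None:
        adata.obs["batch"] = batch
    io_qc.annotate_genes(adata)
    adata.uns["normalized"] = False
    return adata


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study (800 cells, branching lineage, planted
    regulators); generated once per session."""
    return synthetic.generate_dataset()


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced dataset for fast unit-level checks."""
    cfg = synthetic.SyntheticConfig(
        n_cells=300, n_genes=800, targets_per_motif=25.0,
        n_program_genes=40, n_branch_genes=25, n_cycle_genes=15, seed=11,
    )
    return synthetic.generate_dataset(cfg)
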