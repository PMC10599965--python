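import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from smoothscore import ExpressionDataset, GeneSet


def random_sparse_counts(rng, n_cells, n_genes, density=0.3, max_count=20):
    """Random non-negative integer CSR matrix with roughly given density."""
    mask = rng.random((n_cells, n_genes)) < density
    counts = rng.integers(1, max_count + 1, size=(n_cells, n_genes)) * mask
    return sp.csr_matrix(counts.astype(float))


def make_dataset(counts, labels=None, gene_prefix="g", cell_prefix="c"):
    counts = sp.csr_matrix(counts, dtype=float)
    n_cells, n_genes = counts.shape
    gene_ids = [f"{gene_prefix}{i}" for i in range(n_genes)]
    cell_ids = [f"{cell_prefix}{i}" for i in range(n_cells)]
    ann = None
    if labels is not None:
        ann = pd.DataFrame({"label": list(labels)}, index=pd.Index(cell_ids, name="cell_id"))
    return ExpressionDataset(counts, gene_ids, cell_ids, ann)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_dataset():
    """3 cells x 4 genes with known counts and a two-group label."""
    counts = np.array(
        [
            [5.0, 0.0, 2.0, 0.0],
            [0.0, 3.0, 0.0, 1.0],
            [4.0, 4.0, 0.0, 0.0],
        ]
    )
    return make_dataset(counts, labels=["x", "y", "x"])


@pytest.fixture
def marker_geneset():
    return GeneSet("sig", up_genes={"g0", "g2"})
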