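import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from subspot.binning import BinSpec, simple_grid_bin, sliding_window_bin
from subspot.sdge_io import SpatialMatrix
from subspot.synthetic_data import default_fixture


def make_matrix(coords, counts, gene_names=None, layers=None, default_layer="Gene"):
    """Hand-build a small SpatialMatrix from dense counts."""
    counts = np.asarray(counts, dtype=np.int64)
    n, g = counts.shape
    if gene_names is None:
        gene_names = [f"g{j}" for j in range(g)]
    genes = pd.DataFrame(
        {"gene_id": [f"id{j}" for j in range(g)], "gene_name": gene_names}
    )
    all_layers = {default_layer: sp.csr_matrix(counts)}
    if layers:
        all_layers.update({k: sp.csr_matrix(np.asarray(v, dtype=np.int64)) for k, v in layers.items()})
    return SpatialMatrix(
        barcodes=np.array([f"BC{i:04d}" for i in range(n)], dtype=object),
        genes=genes,
        coords=np.asarray(coords, dtype=float),
        layers=all_layers,
        default_layer=default_layer,
    )


@pytest.fixture
def small_matrix():
    """5 barcodes x 4 genes (one mitochondrial) at known positions."""
    coords = [(1.0, 1.0), (12.0, 3.0), (0.1, 0.1), (9.9, 9.9), (25.0, 25.0)]
    counts = [
        [2, 3, 0, 0],
        [0, 0, 4, 0],
        [1, 0, 0, 0],
        [0, 5, 0, 2],
        [0, 0, 0, 7],
    ]
    return make_matrix(coords, counts, gene_names=["geneA", "mt-geneB", "geneC", "geneD"])


@pytest.fixture(scope="session")
def liver_fixture():
    """The default three-stripe fixture: truth, matrix, domain model (seed 0)."""
    return default_fixture(n_barcodes=10_000, n_genes=200, seed=0)


@pytest.fixture(scope="session")
def liver_tracks(liver_fixture):
    """Default two-track binning of the three-stripe fixture."""
    _, matrix, _ = liver_fixture
    grid = simple_grid_bin(matrix, BinSpec(10.0), min_umi=10)
    mssw = sliding_window_bin(matrix, BinSpec(10.0, 2.0))
    return grid, mssw
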