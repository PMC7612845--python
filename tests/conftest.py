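import numpy as np
import pytest
import scipy.sparse as sp

from emh.io import CountMatrix, NormalizedMatrix, normalize


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 genes x 2 cells with entries (g1,c1)=5 and (g3,c2)=2."""
    counts = sp.csc_matrix(np.array([[5, 0], [0, 0], [0, 2]]))
    return CountMatrix(gene_ids=["g1", "g2", "g3"], cell_ids=["c1", "c2"], counts=counts)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def dense_normalized(values: np.ndarray, gene_ids=None, cell_ids=None) -> NormalizedMatrix:
    """Build a NormalizedMatrix directly from a dense nonnegative array."""
    values = np.asarray(values, dtype=float)
    g, c = values.shape
    return NormalizedMatrix(
        gene_ids=gene_ids or [f"g{i}" for i in range(g)],
        cell_ids=cell_ids or [f"c{j}" for j in range(c)],
        values=sp.csc_matrix(values),
    )


def random_counts(rng: np.random.Generator, n_genes: int, n_cells: int,
                  density: float = 0.1) -> CountMatrix:
    mat = sp.random(n_genes, n_cells, density=density, random_state=rng,
                    data_rvs=lambda n: rng.integers(1, 50, n))
    return CountMatrix(
        gene_ids=[f"g{i:05d}" for i in range(n_genes)],
        cell_ids=[f"c{j:05d}" for j in range(n_cells)],
        counts=sp.csc_matrix(mat),
    )


norm_of = normalize  # convenience re-export for tests
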