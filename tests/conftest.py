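import numpy as np
import pytest
import scipy.sparse as sp

from tpscore.io_formats import CountMatrix, GeneSet, GeneSetCollection, Outcome
from tpscore.simulate import SimParams, simulate_counts


@pytest.fixture
def tiny_counts():
    """3 genes x 4 cells with hand-checkable totals."""
    mat = np.array([[0, 1, 2, 0], [2, 0, 1, 3], [3, 4, 0, 1]])
    return CountMatrix(["A", "B", "C"], ["c1", "c2", "c3", "c4"], sp.csr_matrix(mat))


@pytest.fixture(scope="session")
def small_sim():
    """A small but non-trivial two-group simulation for unit tests.

    Higher DE factor spread than the benchmark preset so that signal is
    strong enough to detect with few genes/cells.
    """
    params = SimParams(
        n_genes=120, n_cells=300, de_prob=0.25, de_factor_scale=1.0, seed=7
    )
    return simulate_counts(params)


@pytest.fixture
def separable_outcome():
    rng = np.random.default_rng(0)
    labels = np.array(["a"] * 1000 + ["b"] * 1000)
    cells = [f"c{i}" for i in range(2000)]
    return cells, labels, rng
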