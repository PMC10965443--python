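import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scorpion.io import ExpressionMatrix, PriorEdgeList


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_expr():
    """3 genes x 4 cells with a mix of zeros."""
    counts = np.array(
        [
            [5, 0, 2, 1],
            [0, 3, 0, 0],
            [1, 1, 1, 1],
        ],
        dtype=float,
    )
    return ExpressionMatrix(
        sp.csr_matrix(counts), ["g1", "g2", "g3"], ["c1", "c2", "c3", "c4"]
    )


def make_expr(counts, genes=None, cells=None):
    counts = np.asarray(counts, dtype=float)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    cells = cells or [f"c{j}" for j in range(counts.shape[1])]
    return ExpressionMatrix(sp.csr_matrix(counts), genes, cells)


def make_prior(rows, kind="regulatory"):
    frame = pd.DataFrame(rows, columns=["source", "target", "score"])
    return PriorEdgeList(frame, kind)


@pytest.fixture
def regulatory_prior():
    return make_prior(
        [
            ("A", "g1", 1.0),
            ("A", "g3", 2.0),
            ("B", "g2", 1.5),
            ("B", "g3", 0.5),
        ]
    )


@pytest.fixture
def ppi_prior():
    return make_prior([("A", "B", 0.8)], kind="cooperativity")
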