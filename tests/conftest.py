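import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scshift import CountMatrix, ExpressionMatrix, normalize


def make_counts(values, gene_ids=None, cell_ids=None) -> CountMatrix:
    values = np.asarray(values)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    cell_ids = cell_ids or [f"c{j}" for j in range(values.shape[1])]
    return CountMatrix(
        sp.csr_matrix(values), np.array(gene_ids, dtype=object), np.array(cell_ids, dtype=object)
    )


def make_expr(values, gene_ids=None, cell_ids=None, scale=10_000.0) -> ExpressionMatrix:
    """Wrap a dense array of already log-normalized values."""
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    cell_ids = cell_ids or [f"c{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        sp.csr_matrix(values), np.array(gene_ids, dtype=object), np.array(cell_ids, dtype=object), scale
    )


def two_group_annotation(cell_ids, n_group1, cell_type="typeA", conditions=("control", "perturbed")):
    cond = [conditions[0]] * n_group1 + [conditions[1]] * (len(cell_ids) - n_group1)
    return pd.DataFrame(
        {
            "sample_id": "s0",
            "tissue": "tissue",
            "timepoint": "t0",
            "condition": cond,
            "batch": "b0",
            "cell_type": cell_type,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_counts(rng):
    """50 genes x 80 cells sparse random counts."""
    dense = rng.poisson(0.6, size=(50, 80))
    return make_counts(dense)
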