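import logging

import numpy as np
import pytest

from dc2scape import (
    CountMatrix, ExpressionMatrix, make_branching_traj, make_sc_counts,
)

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def small_counts():
    """300-cell / 300-gene planted-marker dataset shared across tests."""
    counts, truth = make_sc_counts(n_cells=300, n_genes=300, seed=7)
    return counts, truth


@pytest.fixture(scope="session")
def branching():
    """Branching-trajectory expression with latent pseudotime and branches."""
    expr, truth = make_branching_traj(n_cells=400, seed=11)
    return expr, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def toy_counts():
    values = np.array(
        [
            [5, 0, 3, 10],
            [0, 2, 0, 8],
            [1, 1, 1, 1],
            [4, 0, 0, 12],
        ]
    )
    return CountMatrix(
        values=values,
        cell_ids=["c1", "c2", "c3", "c4"],
        gene_ids=["gA", "gB", "gC", "mt-1"],
        mito_mask=np.array([False, False, False, True]),
    )


def expr_from(values, state_tag="normalized"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values=values,
        cell_ids=[f"c{i}" for i in range(values.shape[0])],
        gene_ids=[f"g{j}" for j in range(values.shape[1])],
        state_tag=state_tag,
    )
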