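import numpy as np
import pytest

import hriquant as hq


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def engine128():
    """Shared desk-scale engine (grid 128, the minimum for 128-chromosome
    samples); session-scoped so transition-matrix caches persist."""
    return hq.SFSEngine(n_grid=128)


@pytest.fixture(scope="session")
def selection_grid():
    return hq.SelectionGrid()


@pytest.fixture(scope="session")
def small_gene_set():
    """A 900-gene synthetic genome with known truth, shared across tests."""
    params = hq.SimParams(n_genes=900, n_pop_grid=128)
    genes, truth = hq.simulate_gene_counts(params, seed=2024)
    return params, genes, truth
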