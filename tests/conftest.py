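"""Shared fixtures: small deterministic matrices and cached simulations.

The expensive session-scoped simulations mirror the benchmark conditions
(2,000 cells, biological CV 0.7, log-uniform gene means) and are shared
across test modules so the suite stays within a desk-scale runtime.
"""

import numpy as np
import pytest
import scipy.sparse as sp

from mcfano import (
    CountMatrix,
    SimulationSpec,
    compute_feature_table,
    make_two_group_dataset,
)


@pytest.fixture
def small_counts() -> CountMatrix:
    """4 cells x 3 genes with unequal depths, handy for exact arithmetic."""
    mat = np.array(
        [
            [1, 0, 2],
            [0, 3, 1],
            [2, 1, 0],
            [1, 1, 4],
        ]
    )
    return CountMatrix(sp.csr_matrix(mat))


@pytest.fixture
def equal_depth_counts() -> CountMatrix:
    """Rows are permutations of (0,1,2,3): every cell total is 6."""
    mat = np.array(
        [
            [0, 1, 2, 3],
            [1, 2, 3, 0],
            [2, 3, 0, 1],
            [3, 0, 1, 2],
            [0, 2, 1, 3],
            [3, 1, 2, 0],
        ]
    )
    return CountMatrix(sp.csr_matrix(mat))


@pytest.fixture(scope="session")
def null_sim_2k():
    """Null dataset (no variable genes): 2,000 cells x 2,000 genes, c=0.7."""
    spec = SimulationSpec(n_cells=2000, n_genes=2000, cv=0.7, seed=1)
    return make_two_group_dataset(spec)


@pytest.fixture(scope="session")
def null_sim_5k():
    """Null dataset at the CV-recovery scale: 2,000 cells x 5,000 genes."""
    spec = SimulationSpec(n_cells=2000, n_genes=5000, cv=0.7, seed=3)
    return make_two_group_dataset(spec)


@pytest.fixture(scope="session")
def signal_sim():
    """Benchmark-style dataset: 2,000 cells x 15,000 genes, 1,000 variable."""
    spec = SimulationSpec(
        n_cells=2000, n_genes=15000, n_variable_genes=1000, cv=0.7, seed=11
    )
    return make_two_group_dataset(spec)


@pytest.fixture(scope="session")
def signal_result(signal_sim):
    """Feature table (phi', p-values, FDR) of the benchmark dataset."""
    return compute_feature_table(signal_sim.counts, cv=0.7)


def truth_mask_for(table, dataset) -> np.ndarray:
    """Ground-truth variability flags aligned to a (filtered) feature table."""
    idx = np.array([int(g.split("_")[1]) for g in table["gene_id"]])
    return dataset.variable_gene_mask[idx]
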