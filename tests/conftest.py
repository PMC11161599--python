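import numpy as np
import pytest
import scipy.sparse as sp

from markerbench.io import ClusterAssignment, CountMatrix
from markerbench.prepare import NormMatrix, normalize_log, scale_genes
from markerbench.synthetic import SimConfig, simulate


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 cells x 4 genes with a deliberate zero pattern."""
    values = np.array(
        [
            [5, 0, 2, 0],
            [6, 3, 0, 1],
            [4, 0, 0, 7],
        ]
    )
    return CountMatrix(
        values=sp.csr_matrix(values),
        barcodes=["c1", "c2", "c3"],
        genes=["gA", "gB", "gC", "gD"],
    )


@pytest.fixture
def two_block_norm() -> tuple[NormMatrix, ClusterAssignment]:
    """12 cells in two clusters; gene g0 marks cluster A (cells 0-2)."""
    rng = np.random.default_rng(7)
    X = rng.uniform(0.0, 0.5, size=(12, 6))
    X[:3, 0] = 3.0
    X[3:, 0] = 0.0
    barcodes = [f"c{i}" for i in range(12)]
    labels = {b: ("A" if i < 3 else "B") for i, b in enumerate(barcodes)}
    norm = NormMatrix(values=X, barcodes=barcodes, genes=[f"g{j}" for j in range(6)])
    return norm, ClusterAssignment(labels=labels, cluster_order=["A", "B"])


@pytest.fixture(scope="session")
def sim_small():
    """Seeded 3-cluster simulation, normalized and scaled (session-cached)."""
    cfg = SimConfig(n_cells=240, n_genes=500, n_clusters=3, seed=11)
    matrix, clusters, truth = simulate(cfg)
    norm = scale_genes(normalize_log(matrix))
    return norm, clusters, truth


@pytest.fixture(scope="session")
def sim_recovery():
    """The parameter-recovery study conditions: 5 x 100 cells, 2000 genes."""
    cfg = SimConfig(seed=0)
    matrix, clusters, truth = simulate(cfg)
    norm = scale_genes(normalize_log(matrix))
    return norm, clusters, truth
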