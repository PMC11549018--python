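import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from geees.data_model import (
    AccessibilityMatrix,
    ExpressionMatrix,
    MultiomeData,
    enumerate_candidates,
)
from geees.synthetic import SimConfig, simulate


def make_expr(counts, gene_ids=None, cell_ids=None, tss=None):
    counts = np.asarray(counts)
    G, C = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(G)]
    cell_ids = cell_ids or [f"c{i}" for i in range(C)]
    return ExpressionMatrix(sp.csr_matrix(counts), np.array(gene_ids, dtype=object),
                            np.array(cell_ids, dtype=object), tss)


def make_acc(counts, intervals, cell_ids=None):
    counts = np.asarray(counts)
    peaks = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    cell_ids = cell_ids or [f"c{i}" for i in range(counts.shape[1])]
    return AccessibilityMatrix(sp.csr_matrix(counts), peaks, np.array(cell_ids, dtype=object))


@pytest.fixture(scope="session")
def sim_small():
    """Small planted-coupling dataset shared across read-only tests."""
    return simulate(SimConfig(seed=11, n_cells=150, n_genes=6))


@pytest.fixture(scope="session")
def data_small(sim_small):
    pairs = enumerate_candidates(sim_small.expr, sim_small.acc)
    return MultiomeData(sim_small.expr, sim_small.acc, pairs)


@pytest.fixture(scope="session")
def truth_key(sim_small):
    return set(zip(sim_small.truth.gene_id, sim_small.truth.peak_index))
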