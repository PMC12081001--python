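"""Shared fixtures: small synthetic atlases generated at test time."""

import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from t2atlas.io import CountMatrix, make_gene_annotation
from t2atlas.qc import NormalizedMatrix, log_normalize
from t2atlas.simulate import SimulationConfig, generate_atlas


@pytest.fixture(scope="session")
def small_atlas():
    """A quick 8-cluster atlas (1,200 cells × 400 genes) with ground truth."""
    cfg = SimulationConfig(
        samples=[("f1", "female", 600), ("m1", "male", 600)],
        n_clusters=8,
        n_genes=400,
        seed=7,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_atlas(cfg)


@pytest.fixture(scope="session")
def small_norm(small_atlas):
    matrix, annotation, gene_ann, truth = small_atlas
    return log_normalize(matrix)


@pytest.fixture()
def tiny_counts():
    """Hand-constructed 4-cell × 3-gene count matrix (geneA, geneB, mitoC)."""
    dense = np.array(
        [
            [3, 0, 1],   # 2 genes detected, 25% mito
            [0, 0, 0],   # empty cell
            [5, 5, 0],
            [1, 1, 8],
        ]
    )
    matrix = CountMatrix(sp.csr_matrix(dense), [f"c{i}" for i in range(4)], ["geneA", "geneB", "mitoC"])
    genes = make_gene_annotation(matrix.gene_ids, is_mito={"mitoC": True})
    return matrix, genes


def norm_from_dense(dense, cell_prefix="c", gene_ids=None, scale_factor=1e4):
    """Wrap a dense array of already-log-normalized values for direct tests."""
    dense = np.asarray(dense, dtype=float)
    n, g = dense.shape
    gene_ids = gene_ids or [f"g{j}" for j in range(g)]
    return NormalizedMatrix(
        sp.csr_matrix(dense), [f"{cell_prefix}{i}" for i in range(n)], gene_ids, scale_factor
    )
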