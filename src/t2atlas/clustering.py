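"""PCA embedding and shared-nearest-neighbor graph clustering.

The clustering recipe mirrors the standard single-cell workflow: PCA on the
scaled matrix, a k-nearest-neighbor graph whose edges are reweighted by
neighborhood overlap (Jaccard of the two cells' neighbor sets, pruned below
1/15), and Leiden modularity optimization (RB-configuration) at a
configurable resolution.  The atlas this emulates was clustered at
resolution 12 on ~50k cells; synthetic-scale runs default to 1.0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
import igraph
import leidenalg
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = ["embed_pca", "cluster_cells"]

SNN_PRUNE = 1.0 / 15.0


def embed_pca(scaled: np.ndarray, n_components: int = 50, seed: int = 0) -> np.ndarray:
    """Principal components of the scaled matrix (cells × components).

    Deterministic for a fixed seed; each component's sign is fixed so the
    largest-magnitude gene loading is positive.
    """
    scaled = np.asarray(scaled, dtype=float)
    n_cells, n_genes = scaled.shape
    if n_components > min(n_cells, n_genes):
        raise ValueError(
            f"n_components={n_components} exceeds min(cells, genes)={min(n_cells, n_genes)}"
        )
    pca = PCA(n_components=n_components, svd_solver="randomized", random_state=seed)
    emb = pca.fit_transform(scaled)
    # largest-|loading|-positive sign convention
    comps = pca.components_
    flip = np.sign(comps[np.arange(comps.shape[0]), np.abs(comps).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return emb * flip


def snn_graph(embedding: np.ndarray, k_neighbors: int = 15) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph: Jaccard overlap of kNN sets, pruned."""
    n = embedding.shape[0]
    if n < k_neighbors + 1:
        raise ValueError(f"need at least k_neighbors+1={k_neighbors + 1} cells, got {n}")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(embedding)
    adj = nn.kneighbors_graph(embedding, mode="connectivity")  # includes self
    inter = (adj @ adj.T).tocoo()
    k = k_neighbors + 1
    union = 2 * k - inter.data
    weights = inter.data / union
    keep = weights >= SNN_PRUNE
    g = sp.coo_matrix((weights[keep], (inter.row[keep], inter.col[keep])), shape=(n, n))
    g.setdiag(0)
    g.eliminate_zeros()
    return g.tocsr()


def cluster_cells(
    embedding: np.ndarray,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> pd.Series:
    """Leiden community detection on the SNN graph.

    Returns a Series of contiguous integer cluster ids (0-based, ordered by
    decreasing cluster size) indexed by cell position.  Deterministic for a
    fixed seed; singleton communities are allowed.
    """
    g = snn_graph(embedding, k_neighbors=k_neighbors)
    coo = sp.triu(g, k=1).tocoo()
    graph = igraph.Graph(
        n=g.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    # relabel by decreasing size, ties by first appearance, ids contiguous from 0
    order = pd.Series(labels).value_counts(sort=True).index
    remap = {old: new for new, old in enumerate(order)}
    return pd.Series([remap[x] for x in labels], name="cluster")
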