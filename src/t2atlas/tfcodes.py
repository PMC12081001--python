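"""Binarized transcription-factor combinatorial-code analysis.

Per structural TF class, every TF that is a significant positive marker of a
cluster gets a 1 in that cluster's code and 0 elsewhere; TFs that mark no
cluster are retained as all-zero columns so the code dimension is the class
size.  A cluster's code is *unique* when no other cluster shares the exact
row.  Pairwise similarity is the Jaccard index of the clusters' "on"-TF
sets, with the both-empty pair defined as 1 (identical codes must not look
maximally dissimilar); heatmap ordering is the leaf order of average-linkage
hierarchical clustering on distance 1 − J.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list, optimal_leaf_ordering
from scipy.spatial.distance import squareform

from .io import TF_CLASSES

__all__ = [
    "BinaryCode",
    "binarize_tf_markers",
    "count_unique_codes",
    "shared_code_groups",
    "jaccard_matrix",
    "order_by_similarity",
]


@dataclass
class BinaryCode:
    """Clusters × TFs 0/1 matrix for one TF class."""

    tf_class: str
    matrix: np.ndarray
    cluster_ids: list
    tf_ids: list

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if not np.isin(self.matrix, [0, 1]).all():
            raise ValueError("code entries must be 0/1")
        self.matrix = self.matrix.astype(np.int8)
        if self.matrix.shape != (len(self.cluster_ids), len(self.tf_ids)):
            raise ValueError("code shape does not match axis labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.cluster_ids, columns=self.tf_ids)


def binarize_tf_markers(
    markers: pd.DataFrame,
    genes: pd.DataFrame,
    tf_class: str,
    cluster_ids=None,
    alpha: float = 0.05,
) -> BinaryCode:
    """Build the clusters × TFs binary code for one TF class.

    ``entry(c, t) = 1`` iff TF ``t`` of the class is a positive marker of
    cluster ``c`` with ``p_adj < alpha`` (the marker table must come from
    positive mode, so enrichment direction is already enforced upstream).
    ``cluster_ids`` fixes the row universe; by default the clusters present
    in the marker table are used.
    """
    if tf_class not in TF_CLASSES:
        raise ValueError(f"unknown tf_class {tf_class!r}")
    tf_ids = sorted(genes.index[genes["tf_class"] == tf_class])
    if not tf_ids:
        raise ValueError(f"annotation contains no TFs of class {tf_class!r}")
    if cluster_ids is None:
        cluster_ids = sorted(markers["cluster"].unique())
    cluster_ids = list(cluster_ids)
    code = np.zeros((len(cluster_ids), len(tf_ids)), dtype=np.int8)
    hits = markers[markers["gene"].isin(tf_ids) & (markers["p_adj"] < alpha)]
    row_of = {c: i for i, c in enumerate(cluster_ids)}
    col_of = {t: j for j, t in enumerate(tf_ids)}
    for _, rec in hits.iterrows():
        if rec["cluster"] in row_of:
            code[row_of[rec["cluster"]], col_of[rec["gene"]]] = 1
    return BinaryCode(tf_class, code, cluster_ids, tf_ids)


def _row_keys(code: BinaryCode) -> list:
    return [tuple(row) for row in code.matrix]


def count_unique_codes(code: BinaryCode) -> tuple[int, float]:
    """(number of clusters with an unshared code, percentage to one decimal)."""
    n = len(code.cluster_ids)
    if n == 0:
        raise ValueError("no clusters")
    keys = _row_keys(code)
    counts = pd.Series(keys).value_counts()
    n_unique = int(sum(counts[k] == 1 for k in set(keys)))
    pct = round(100.0 * n_unique / n, 1)
    return n_unique, pct


def shared_code_groups(code: BinaryCode) -> list:
    """Groups (size >= 2) of clusters with identical codes, sorted by smallest member."""
    groups: dict = {}
    for cid, key in zip(code.cluster_ids, _row_keys(code)):
        groups.setdefault(key, []).append(cid)
    shared = [sorted(g) for g in groups.values() if len(g) >= 2]
    return sorted(shared, key=lambda g: g[0])


def jaccard_matrix(code: BinaryCode) -> pd.DataFrame:
    """Pairwise Jaccard index of the clusters' on-TF sets (both-empty → 1)."""
    m = code.matrix.astype(float)
    inter = m @ m.T
    sizes = m.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
    np.fill_diagonal(jac, 1.0)
    return pd.DataFrame(jac, index=code.cluster_ids, columns=code.cluster_ids)


def order_by_similarity(jac: pd.DataFrame) -> list:
    """Cluster ordering for similarity heatmaps.

    Average-linkage hierarchical clustering on distance 1 − J; the
    dendrogram leaf order is returned (optimal leaf ordering for
    determinism and tight blocks).  Ties in the distance matrix resolve
    toward smaller cluster ids because input order feeds the linkage.
    """
    if len(jac) < 2:
        raise ValueError("ordering requires at least 2 clusters")
    dist = 1.0 - jac.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2  # guard tiny asymmetries
    condensed = squareform(dist, checks=False)
    link = average(condensed)
    link = optimal_leaf_ordering(link, condensed)
    return [jac.index[i] for i in leaves_list(link)]
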