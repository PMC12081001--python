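"""One-vs-rest marker gene ranking.

For each cluster and gene the test is a two-sided Wilcoxon rank-sum of
in-cluster versus all-other cells on log-normalized values, after a fold
change / detection prefilter.  The fold change is computed on expm1 of the
log-normalized means, ``log2((m_in + eps) / (m_out + eps))`` with
``eps = 1e-9`` — the convention of the standard single-cell toolchain whose
tables this reproduces.  Benjamini–Hochberg adjustment is applied within
each cluster over the genes actually tested.  When both groups hold at most
8 cells the exact tie-aware rank-sum null is used; otherwise the normal
approximation with tie correction (vectorized over genes).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm as normal, rankdata

from ._stats import EXACT_MAX_GROUP, bh_adjust, rank_sum_test
from .qc import NormalizedMatrix

__all__ = ["rank_markers", "top_markers"]

LOG2FC_EPS = 1e-9

MARKER_COLUMNS = ["cluster", "gene", "log2fc", "pct_in", "pct_out", "p_value", "p_adj"]


def rank_markers(
    norm: NormalizedMatrix,
    clusters: pd.Series,
    min_pct: float = 0.1,
    min_log2fc: float = 0.25,
    mode: str = "positive",
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker table over all clusters.

    Parameters
    ----------
    norm
        Log-normalized expression.
    clusters
        Cluster label per cell (indexed by cell id, or positionally aligned).
    min_pct, min_log2fc
        Prefilters: a gene is tested for a cluster when its in-cluster
        detection fraction is at least ``min_pct`` and its fold change passes
        ``min_log2fc`` (in ``positive`` mode: ``log2fc >= min_log2fc``; in
        ``signed`` mode: either detection fraction suffices and
        ``|log2fc| >= min_log2fc``).
    mode
        ``"positive"`` (enriched markers only) or ``"signed"`` (both
        directions, shared thresholds).

    Returns a DataFrame with columns cluster, gene, log2fc, pct_in, pct_out,
    p_value, p_adj, sorted by cluster id then gene id.  Clusters with fewer
    than 3 cells are skipped with a warning.
    """
    if mode not in ("positive", "signed"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = _align_labels(norm, clusters)
    cluster_ids = sorted(pd.unique(labels))
    if len(cluster_ids) < 2:
        raise ValueError("marker ranking requires at least 2 clusters")

    X = norm.X.tocsc()
    n_cells, n_genes = X.shape
    expm1 = X.copy()
    expm1.data = np.expm1(expm1.data)
    total_expm1 = np.asarray(expm1.sum(axis=0)).ravel()
    total_nnz = np.asarray((X > 0).sum(axis=0)).ravel()

    dense = None  # dense log-norm values, materialized lazily for rank tests
    ranks = None
    tie_var_factor = None

    records = []
    for c in cluster_ids:
        in_mask = labels == c
        n_in = int(in_mask.sum())
        n_out = n_cells - n_in
        if n_in < 3:
            warnings.warn(f"cluster {c} has {n_in} < 3 cells; markers skipped")
            continue
        sum_in = np.asarray(expm1[in_mask].sum(axis=0)).ravel()
        nnz_in = np.asarray((X[in_mask] > 0).sum(axis=0)).ravel()
        mean_in = sum_in / n_in
        mean_out = (total_expm1 - sum_in) / n_out
        pct_in = nnz_in / n_in
        pct_out = (total_nnz - nnz_in) / n_out
        log2fc = np.log2((mean_in + LOG2FC_EPS) / (mean_out + LOG2FC_EPS))

        if mode == "positive":
            tested = (pct_in >= min_pct) & (log2fc >= min_log2fc)
        else:
            tested = ((pct_in >= min_pct) | (pct_out >= min_pct)) & (
                np.abs(log2fc) >= min_log2fc
            )
        tested_idx = np.flatnonzero(tested)
        if tested_idx.size == 0:
            continue

        if dense is None:
            dense = np.asarray(X.todense())
        if n_in <= EXACT_MAX_GROUP and n_out <= EXACT_MAX_GROUP:
            p = np.array(
                [
                    rank_sum_test(dense[in_mask, j], dense[~in_mask, j])
                    for j in tested_idx
                ]
            )
        else:
            if ranks is None:
                ranks, tie_var_factor = _prepare_ranks(dense)
            p = _asymptotic_p(ranks, tie_var_factor, in_mask, tested_idx)

        p_adj = bh_adjust(p)
        for j, pj, qj in zip(tested_idx, p, p_adj):
            records.append(
                (c, norm.gene_ids[j], log2fc[j], pct_in[j], pct_out[j], pj, qj)
            )

    table = pd.DataFrame(records, columns=MARKER_COLUMNS)
    return table.sort_values(["cluster", "gene"], kind="stable").reset_index(drop=True)


def _align_labels(norm: NormalizedMatrix, clusters: pd.Series) -> np.ndarray:
    s = pd.Series(clusters)
    if s.index.equals(pd.RangeIndex(len(s))) and not s.index.equals(norm.cell_ids):
        if len(s) != norm.n_cells:
            raise ValueError("cluster labels do not align with cells")
        return s.to_numpy()
    aligned = s.reindex(norm.cell_ids)
    if aligned.isna().any():
        raise ValueError("every cell must have a cluster label")
    return aligned.to_numpy()


def _prepare_ranks(dense: np.ndarray):
    """Per-gene midranks over all cells plus the tie-corrected variance factor."""
    n = dense.shape[0]
    ranks = rankdata(dense, axis=0)
    # tie correction: sum(t^3 - t) per gene over tied groups
    tie_terms = np.empty(dense.shape[1])
    for j in range(dense.shape[1]):
        _, counts = np.unique(dense[:, j], return_counts=True)
        tie_terms[j] = (counts.astype(float) ** 3 - counts).sum()
    tie_var_factor = (n + 1) - tie_terms / (n * (n - 1))
    return ranks, tie_var_factor


def _asymptotic_p(ranks, tie_var_factor, in_mask, tested_idx):
    n = ranks.shape[0]
    n_in = int(in_mask.sum())
    n_out = n - n_in
    w = ranks[np.ix_(in_mask, tested_idx)].sum(axis=0)
    mu = n_in * (n + 1) / 2.0
    var = n_in * n_out / 12.0 * tie_var_factor[tested_idx]
    p = np.ones_like(w, dtype=float)
    ok = var > 0
    z = np.zeros_like(w, dtype=float)
    z[ok] = (w[ok] - mu) / np.sqrt(var[ok])
    p[ok] = np.minimum(1.0, 2.0 * normal.sf(np.abs(z[ok])))
    return p


def top_markers(table: pd.DataFrame, n: int = 10) -> dict:
    """Per-cluster ordered top marker genes.

    Genes are sorted by ascending adjusted p, then descending log2fc, then
    gene id (a total order); the first ``n`` are returned per cluster.
    """
    if table.empty:
        raise ValueError("marker table is empty")
    out = {}
    for c, grp in table.groupby("cluster", sort=True):
        ordered = grp.sort_values(
            ["p_adj", "log2fc", "gene"], ascending=[True, False, True], kind="stable"
        )
        out[c] = ordered["gene"].head(n).tolist()
    return out
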