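"""Cell QC, log-normalization, gene scaling, and cluster-level summaries.

Conventions (fixed, documented):

* QC keeps cells with ``min_genes <= n_genes_detected <= max_genes`` and
  ``pct_mito <= max_pct_mito`` — boundaries inclusive, because the filter
  removes strict violations ("fewer than 200", "more than 2500", "more than
  5%").
* Normalization is natural log of 1 + counts-per-``scale_factor`` (default
  1e4), the convention of the standard single-cell toolchain.
* Scaling uses the sample (n−1) standard deviation; zero-variance genes map
  to 0; values are clipped to ±``clip``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix

__all__ = [
    "NormalizedMatrix",
    "compute_cell_qc",
    "filter_cells",
    "log_normalize",
    "scale_genes",
    "select_hvgs",
    "scaled_average_expression",
]


@dataclass
class NormalizedMatrix:
    """Log-normalized expression, cells × genes; zeros stay exactly zero."""

    X: sp.csr_matrix
    cell_ids: pd.Index
    gene_ids: pd.Index
    scale_factor: float = 1e4

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.cell_ids = pd.Index(self.cell_ids)
        self.gene_ids = pd.Index(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def gene_vector(self, gene_id: str) -> np.ndarray:
        j = self.gene_ids.get_loc(gene_id)
        return np.asarray(self.X[:, j].todense()).ravel()

    def subset_cells(self, mask_or_index) -> "NormalizedMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NormalizedMatrix(self.X[idx], self.cell_ids[idx], self.gene_ids, self.scale_factor)


def compute_cell_qc(matrix: CountMatrix, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-cell QC table: genes detected, percent mitochondrial counts.

    ``genes`` is the gene annotation (must carry ``is_mito``).  A cell with
    zero total counts gets ``pct_mito = 0`` and triggers a warning.
    Returns a DataFrame indexed by cell id with columns ``n_genes_detected``,
    ``pct_mito``.
    """
    mito_mask = genes.reindex(matrix.gene_ids)["is_mito"].to_numpy(dtype=bool)
    X = matrix.X
    n_detected = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel().astype(float)
    mito_totals = np.asarray(X[:, mito_mask].sum(axis=1)).ravel().astype(float)
    pct = np.zeros_like(totals)
    nz = totals > 0
    pct[nz] = 100.0 * mito_totals[nz] / totals[nz]
    if np.any(~nz):
        warnings.warn(f"{int((~nz).sum())} cell(s) with zero total counts; pct_mito set to 0")
    return pd.DataFrame(
        {"n_genes_detected": n_detected, "pct_mito": pct},
        index=pd.Index(matrix.cell_ids, name="cell_id"),
    )


def filter_cells(
    matrix: CountMatrix,
    qc: pd.DataFrame,
    min_genes: int = 200,
    max_genes: int = 2500,
    max_pct_mito: float = 5.0,
) -> CountMatrix:
    """Drop low-quality cells; boundaries are inclusive; order preserved."""
    qc = qc.reindex(matrix.cell_ids)
    keep = (
        (qc["n_genes_detected"] >= min_genes)
        & (qc["n_genes_detected"] <= max_genes)
        & (qc["pct_mito"] <= max_pct_mito)
    ).to_numpy()
    if not keep.any():
        warnings.warn("QC filter removed every cell")
    return matrix.subset_cells(keep)


def log_normalize(matrix: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """``ln(1 + count * scale_factor / cell_total)`` per entry.

    Cells with zero total counts are an error (filter first); the message
    names the offending cells.
    """
    totals = np.asarray(matrix.X.sum(axis=1)).ravel().astype(float)
    if np.any(totals == 0):
        bad = matrix.cell_ids[totals == 0].tolist()
        raise ValueError(f"cells with zero total counts cannot be normalized: {bad[:10]}")
    X = sp.csr_matrix(matrix.X, dtype=float)
    scale = scale_factor / totals
    X = sp.diags(scale) @ X
    X.data = np.log1p(X.data)
    return NormalizedMatrix(X, matrix.cell_ids, matrix.gene_ids, scale_factor)


def scale_genes(norm: NormalizedMatrix, clip: float = 10.0) -> np.ndarray:
    """Z-score each gene over cells (sample sd; sd=0 → 0), clip to ±clip.

    Returns a dense cells × genes float array.
    """
    if norm.n_cells < 2:
        raise ValueError("scaling requires at least 2 cells")
    X = np.asarray(norm.X.todense(), dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    out = X - mean
    nz = sd > 0
    out[:, nz] /= sd[nz]
    out[:, ~nz] = 0.0
    np.clip(out, -clip, clip, out=out)
    return out


def select_hvgs(norm: NormalizedMatrix, n_top: int = 1000, n_bins: int = 20) -> np.ndarray:
    """Highly-variable gene selection by binned standardized dispersion.

    Genes are ranked by the z-score of their dispersion (variance / mean of
    log-normalized expression) within ``n_bins`` mean-expression quantile
    bins, which removes the mean–variance trend so biological variability —
    not expression level — drives the ranking.  Returns the column indices
    of the top ``n_top`` genes (all genes when ``n_top`` >= n_genes or 0).
    Restricting scaling/PCA to these genes is what keeps sparse cluster
    programs above the noise floor of the embedding.
    """
    if n_top <= 0 or n_top >= norm.n_genes:
        return np.arange(norm.n_genes)
    X = np.asarray(norm.X.todense())
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    bins = pd.qcut(pd.Series(mean), min(n_bins, max(norm.n_genes // 10, 1)), duplicates="drop")
    z = (
        pd.Series(disp)
        .groupby(bins, observed=True)
        .transform(lambda s: (s - s.mean()) / (s.std() if s.std() > 0 else 1.0))
        .fillna(0.0)
        .to_numpy()
    )
    order = np.argsort(-z, kind="stable")
    return np.sort(order[:n_top])


def scaled_average_expression(norm: NormalizedMatrix, clusters: pd.Series) -> pd.DataFrame:
    """Cluster-mean log-normalized expression, z-scored across clusters per gene.

    ``clusters`` maps every cell id to a cluster label.  Empty clusters are
    excluded with a warning.  Genes constant across clusters scale to 0.
    Returns a clusters × genes DataFrame; this is the "scaled average
    expression" quantity whose positivity drives enhancer-gene identity
    mapping.
    """
    labels = clusters.reindex(norm.cell_ids)
    if labels.isna().any():
        raise ValueError("every cell must be assigned a cluster")
    cluster_ids = sorted(labels.unique())
    means = np.zeros((len(cluster_ids), norm.n_genes))
    for i, c in enumerate(cluster_ids):
        mask = (labels == c).to_numpy()
        means[i] = np.asarray(norm.X[mask].mean(axis=0)).ravel()
    mean_over = means.mean(axis=0)
    sd_over = means.std(axis=0, ddof=1) if len(cluster_ids) > 1 else np.zeros(norm.n_genes)
    scaled = means - mean_over
    nz = sd_over > 0
    scaled[:, nz] /= sd_over[nz]
    scaled[:, ~nz] = 0.0
    return pd.DataFrame(scaled, index=pd.Index(cluster_ids, name="cluster"), columns=norm.gene_ids)
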