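"""Neurotransmitter co-expression, neuropeptide programs, TF–NP correlation.

Each fast-acting neurotransmitter system is read out through a single
marker gene: VGlut (glutamatergic), VAChT (cholinergic), Gad1 (GABAergic),
Tbh (tyraminergic), ple (dopaminergic), SerT (serotonergic) and Tdc2
(octopaminergic) — the role labels follow the atlas this emulates, even
where the canonical enzyme-to-transmitter mapping differs.  A cell carries a
role when the marker's log-normalized expression exceeds a threshold
(default 2.0); the threshold is applied on the log-normalized scale because
the "none" class is defined there, but a z-scored mode is available.
Counting every observed role combination (including "none") yields the
UpSet table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import NT_ROLE_OF_GENE, NT_ROLES
from .qc import NormalizedMatrix, scale_genes

__all__ = [
    "classify_neurotransmitters",
    "coexpression_counts",
    "select_cluster_defining_np",
    "tf_np_correlation",
]


def classify_neurotransmitters(
    norm: NormalizedMatrix,
    genes: pd.DataFrame,
    threshold: float = 2.0,
    scale: str = "lognorm",
) -> pd.DataFrame:
    """Per-cell neurotransmitter role profile.

    Returns a boolean cells × 7-role DataFrame; a cell carries role R iff
    the log-normalized (or, with ``scale="scaled"``, z-scored) value of R's
    marker gene exceeds ``threshold``.  All 7 marker genes must be present
    in the annotation's ``nt_role`` column.
    """
    if scale not in ("lognorm", "scaled"):
        raise ValueError(f"unknown scale {scale!r}")
    ann = genes.reindex(norm.gene_ids)
    role_gene = {}
    for gene_id, role in ann["nt_role"].items():
        if role != "none":
            role_gene[role] = gene_id
    missing = [r for r in NT_ROLES if r not in role_gene]
    if missing:
        raise ValueError(f"missing neurotransmitter marker genes for roles: {missing}")
    cols = [norm.gene_ids.get_loc(role_gene[r]) for r in NT_ROLES]
    if scale == "scaled":
        values = scale_genes(norm)[:, cols]
    else:
        values = np.asarray(norm.X[:, cols].todense())
    profile = pd.DataFrame(
        values > threshold,
        index=pd.Index(norm.cell_ids, name="cell_id"),
        columns=list(NT_ROLES),
    )
    profile.attrs["threshold"] = threshold
    profile.attrs["scale"] = scale
    return profile


def coexpression_counts(profile: pd.DataFrame) -> pd.DataFrame:
    """Exact UpSet counts of every observed role combination.

    The empty combination is reported as ``"none"``.  Rows are ordered by
    descending count, ties broken lexicographically by combination label.
    Percentages sum to 100 over all cells.
    """
    if profile.empty:
        raise ValueError("empty neurotransmitter profile")
    labels = profile.apply(
        lambda row: "+".join(profile.columns[row.to_numpy(dtype=bool)]) or "none", axis=1
    )
    counts = labels.value_counts()
    table = pd.DataFrame(
        {"combination": counts.index, "count": counts.to_numpy()}
    ).sort_values(["count", "combination"], ascending=[False, True], kind="stable")
    table["percentage"] = 100.0 * table["count"] / len(profile)
    return table.reset_index(drop=True)


def select_cluster_defining_np(
    markers: pd.DataFrame,
    genes: pd.DataFrame,
    max_clusters: int = 5,
    alpha: float = 0.05,
    min_log2fc: float = 1.0,
) -> dict:
    """Neuropeptides enriched in a limited number of clusters.

    A neuropeptide qualifies when it is a significant positive marker
    (``p_adj < alpha`` and ``log2fc >= min_log2fc``) in at least 1 and at
    most ``max_clusters`` clusters.  Returns neuropeptide → sorted cluster
    list.
    """
    np_genes = set(genes.index[genes["is_neuropeptide"]])
    hits = markers[
        markers["gene"].isin(np_genes)
        & (markers["p_adj"] < alpha)
        & (markers["log2fc"] >= min_log2fc)
    ]
    out = {}
    for gene, grp in hits.groupby("gene"):
        cluster_list = sorted(grp["cluster"].unique())
        if 1 <= len(cluster_list) <= max_clusters:
            out[gene] = cluster_list
    return out


def tf_np_correlation(
    norm: NormalizedMatrix,
    genes: pd.DataFrame,
    top_n: int = 5,
    method: str = "pearson",
) -> tuple[pd.DataFrame, dict]:
    """Correlation of every TF with every neuropeptide across all cells.

    Returns ``(corr, top)`` where ``corr`` is a neuropeptides × TFs
    DataFrame of coefficients (NaN rows flag zero-variance neuropeptides)
    and ``top`` maps each neuropeptide to its ``top_n`` TFs by descending
    coefficient (ties by gene id).  Zero-variance TFs are excluded from the
    ranking; Spearman is available alongside Pearson.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    ann = genes.reindex(norm.gene_ids)
    tf_ids = [g for g in norm.gene_ids if ann.loc[g, "tf_class"] != "none"]
    np_ids = [g for g in norm.gene_ids if ann.loc[g, "is_neuropeptide"]]
    if norm.n_cells < 3:
        raise ValueError("correlation requires at least 3 cells")
    if not tf_ids or not np_ids:
        raise ValueError("need at least one TF and one neuropeptide gene")

    cols = [norm.gene_ids.get_loc(g) for g in np_ids + tf_ids]
    values = np.asarray(norm.X[:, cols].todense(), dtype=float)
    if method == "spearman":
        from scipy.stats import rankdata

        values = rankdata(values, axis=0)
    values = values - values.mean(axis=0)
    sd = values.std(axis=0)
    n_np = len(np_ids)
    np_block, tf_block = values[:, :n_np], values[:, n_np:]
    sd_np, sd_tf = sd[:n_np], sd[n_np:]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (np_block.T @ tf_block) / len(values)
        corr /= np.outer(sd_np, sd_tf)
    corr = pd.DataFrame(corr, index=pd.Index(np_ids, name="neuropeptide"), columns=tf_ids)

    valid_tfs = [t for t, s in zip(tf_ids, sd_tf) if s > 0]
    top = {}
    for npep in np_ids:
        row = corr.loc[npep, valid_tfs]
        if row.isna().all():
            top[npep] = None  # zero-variance neuropeptide: flagged, not dropped
            continue
        ranked = row.to_frame("r").reset_index(names="tf")
        ranked = ranked.sort_values(["r", "tf"], ascending=[False, True], kind="stable")
        top[npep] = ranked["tf"].head(top_n).tolist()
    return corr, top
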