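"""Cluster identity mapping: bulk correlation, enhancer genes, marker queries,
and glial marker panels.

Bulk-reference matching is plain Pearson correlation between each cluster's
mean log-normalized profile and each reference profile over a shared gene
subset (default: the most variable genes across clusters); each cluster is
assigned the neuron type with the highest defined coefficient.  Split-Gal4
enhancer-gene mapping and marker-constraint queries both operate on the
scaled (z-scored across clusters) average expression, reading "positive
expression" literally as > 0 on that scale and "negative" as <= 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qc import NormalizedMatrix

__all__ = [
    "BulkReference",
    "correlate_bulk",
    "assign_identity_by_max",
    "map_enhancer_genes",
    "query_marker_constraints",
    "select_marker_positive_clusters",
    "annotate_by_marker_panel",
    "cluster_mean_profiles",
    "most_variable_genes",
]


@dataclass
class BulkReference:
    """Log-scale mean expression profiles of named neuron types (types × genes)."""

    profiles: pd.DataFrame  # index: neuron_type, columns: gene ids

    def __post_init__(self) -> None:
        if self.profiles.index.has_duplicates:
            raise ValueError("duplicate neuron_type in bulk reference")

    @property
    def neuron_types(self) -> list:
        return self.profiles.index.tolist()


def cluster_mean_profiles(norm: NormalizedMatrix, clusters: pd.Series) -> pd.DataFrame:
    """Clusters × genes mean log-normalized expression."""
    labels = pd.Series(clusters).reindex(norm.cell_ids)
    rows = {}
    for c in sorted(labels.dropna().unique()):
        mask = (labels == c).to_numpy()
        rows[c] = np.asarray(norm.X[mask].mean(axis=0)).ravel()
    return pd.DataFrame.from_dict(rows, orient="index", columns=norm.gene_ids)


def most_variable_genes(cluster_profiles: pd.DataFrame, n: int = 2000) -> list:
    """Genes with the highest variance across cluster mean profiles."""
    var = cluster_profiles.var(axis=0, ddof=1)
    return var.sort_values(ascending=False, kind="stable").head(n).index.tolist()


def correlate_bulk(
    cluster_profiles: pd.DataFrame,
    reference: BulkReference,
    gene_subset=None,
    n_variable: int = 2000,
) -> pd.DataFrame:
    """Pearson r between every cluster profile and every reference profile.

    ``gene_subset`` restricts the comparison; by default the top
    ``n_variable`` most variable genes across clusters (intersected with the
    reference's gene universe) are used.  Zero-variance vectors yield NaN
    coefficients, flagged rather than dropped.
    """
    if gene_subset is None:
        gene_subset = most_variable_genes(cluster_profiles, n_variable)
    shared = [g for g in gene_subset if g in reference.profiles.columns and g in cluster_profiles.columns]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes after subsetting; need >= 3")
    A = cluster_profiles[shared].to_numpy(dtype=float)
    B = reference.profiles[shared].to_numpy(dtype=float)
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((A**2).sum(axis=1))
    sb = np.sqrt((B**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (A @ B.T) / np.outer(sa, sb)
    r[:, sb == 0] = np.nan
    r[sa == 0, :] = np.nan
    return pd.DataFrame(r, index=cluster_profiles.index, columns=reference.neuron_types)


def assign_identity_by_max(coefficients: pd.DataFrame) -> pd.DataFrame:
    """Assign each cluster the neuron type with the highest defined coefficient.

    Ties break toward the earlier reference column (logged).  Clusters whose
    coefficients are all undefined are returned unassigned with a warning.
    Multiple clusters may share one type.
    """
    records = []
    for cluster, row in coefficients.iterrows():
        if row.isna().all():
            warnings.warn(f"cluster {cluster}: all coefficients undefined; unassigned")
            records.append((cluster, None, np.nan))
            continue
        best = row.max()
        winners = row.index[row == best]
        if len(winners) > 1:
            warnings.warn(
                f"cluster {cluster}: coefficient tie between {list(winners)}; "
                "keeping first by reference order"
            )
        records.append((cluster, winners[0], float(best)))
    out = pd.DataFrame(records, columns=["cluster", "neuron_type", "coefficient"])
    out["method"] = "bulk_correlation"
    return out


def map_enhancer_genes(scaled_avg: pd.DataFrame, drivers: pd.DataFrame) -> dict:
    """Candidate clusters per split-Gal4 driver.

    ``drivers`` has columns ``driver_id``, ``neuron_type``,
    ``enhancer_genes`` (list of gene symbols).  A cluster is a candidate for
    a driver iff EVERY enhancer gene has scaled average expression > 0 in
    that cluster; candidates are sorted by descending minimum scaled average
    over the driver's genes.  Drivers naming absent genes are skipped with a
    warning.
    """
    out = {}
    for _, rec in drivers.iterrows():
        genes = list(rec["enhancer_genes"])
        if not genes:
            warnings.warn(f"driver {rec['driver_id']}: empty enhancer gene list; skipped")
            continue
        missing = [g for g in genes if g not in scaled_avg.columns]
        if missing:
            warnings.warn(
                f"driver {rec['driver_id']}: enhancer gene(s) {missing} absent; skipped"
            )
            continue
        block = scaled_avg[genes]
        min_val = block.min(axis=1)
        candidates = min_val[(block > 0).all(axis=1)]
        out[rec["driver_id"]] = candidates.sort_values(ascending=False, kind="stable").index.tolist()
    return out


def query_marker_constraints(
    scaled_avg: pd.DataFrame,
    constraints: list,
    driver_genes=None,
) -> list:
    """Clusters satisfying signed marker constraints.

    ``constraints`` is a list of ``(gene, sign)`` with sign ``"+"`` (scaled
    average > 0) or ``"-"`` (<= 0); ``driver_genes`` adds "+" constraints.
    Returns matching cluster ids in ascending order.
    """
    cons = [(g, s) for g, s in constraints]
    for g in driver_genes or []:
        cons.append((g, "+"))
    if not cons:
        warnings.warn("empty constraint list: every cluster matches")
        return sorted(scaled_avg.index.tolist())
    missing = [g for g, _ in cons if g not in scaled_avg.columns]
    if missing:
        raise ValueError(f"constraint gene(s) not in table: {missing}")
    signs = {}
    for g, s in cons:
        if s not in ("+", "-"):
            raise ValueError(f"constraint sign must be '+' or '-', got {s!r}")
        if signs.setdefault(g, s) != s:
            warnings.warn(f"contradictory constraints on {g}; no cluster can match")
            return []
    mask = pd.Series(True, index=scaled_avg.index)
    for g, s in signs.items():
        mask &= scaled_avg[g] > 0 if s == "+" else scaled_avg[g] <= 0
    return sorted(scaled_avg.index[mask].tolist())


def select_marker_positive_clusters(
    norm: NormalizedMatrix,
    clusters: pd.Series,
    marker_gene: str,
    min_mean: float = 1.0,
    min_pct: float = 0.5,
) -> list:
    """Clusters expressing a marker (e.g. the pan-glial gene repo) broadly.

    A cluster is selected when the marker's mean log-normalized expression
    is >= ``min_mean`` AND the fraction of expressing cells is >=
    ``min_pct``.  Used to subset repo+ cells for glial re-clustering.
    """
    if marker_gene not in norm.gene_ids:
        raise ValueError(f"marker gene {marker_gene!r} not present")
    vec = norm.gene_vector(marker_gene)
    labels = pd.Series(clusters).reindex(norm.cell_ids).to_numpy()
    selected = []
    for c in sorted(pd.unique(labels[~pd.isna(labels)])):
        vals = vec[labels == c]
        if vals.mean() >= min_mean and (vals > 0).mean() >= min_pct:
            selected.append(c)
    return selected


def annotate_by_marker_panel(
    scaled_avg: pd.DataFrame,
    panels: dict,
    min_positive_frac: float = 0.5,
) -> dict:
    """Glial subtype labels from marker panels.

    A cluster gets subtype S when at least ``min_positive_frac`` of S's
    panel genes have scaled average expression > 0; clusters qualifying for
    several subtypes get a joined ``"A/B"`` label (overlapping identities),
    and clusters qualifying for none are ``"unannotated"``.  Panel genes
    absent from the table are dropped from that panel with a warning.
    """
    usable = {}
    for subtype, genes in panels.items():
        present = [g for g in genes if g in scaled_avg.columns]
        absent = sorted(set(genes) - set(present))
        if absent:
            warnings.warn(f"panel {subtype}: dropping absent gene(s) {absent}")
        if present:
            usable[subtype] = present
    if not usable:
        raise ValueError("no usable marker panels")
    labels = {}
    for cluster in scaled_avg.index:
        hits = [
            s
            for s, genes in usable.items()
            if (scaled_avg.loc[cluster, genes] > 0).mean() >= min_positive_frac
        ]
        labels[cluster] = "/".join(hits) if hits else "unannotated"
    return labels
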