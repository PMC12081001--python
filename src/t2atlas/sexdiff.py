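"""Sex-biased cluster detection and pseudobulk sex differential expression.

Female and male nuclei come from separate samples; mixed-sex samples are
excluded because their nuclei cannot be assigned a sex.  Bias detection
normalizes for unequal input nuclei between the sexes: under the null every
cluster draws males at the global rate q = N_male / (N_male + N_female), and
a cluster is called biased when a BH-adjusted two-sided exact binomial test
rejects AND the input-normalized fold change clears a cutoff (the source
analysis states no statistical criterion for "disproportionate"; both knobs
are exposed).

Pseudobulk DE aggregates counts per (cluster, sex), converts to CPM, and
treats clusters as paired replicates: per gene, the per-cluster
log2((cpm_f + 1) / (cpm_m + 1)) is averaged and a two-sided Wilcoxon
signed-rank across cluster pairs gives the p-value, BH-adjusted over genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from ._stats import bh_adjust, binom_test_two_sided
from .io import CountMatrix

__all__ = ["sex_bias_clusters", "pseudobulk_sex_de", "PseudobulkResult"]

SEX_BIAS_COLUMNS = [
    "cluster",
    "n_female_raw",
    "n_male_raw",
    "n_female_norm",
    "n_male_norm",
    "male_fraction_norm",
    "log2_ratio",
    "p_value",
    "p_adj",
    "biased",
]


def sex_bias_clusters(
    annotation: pd.DataFrame,
    clusters: pd.Series,
    alpha: float = 0.05,
    min_abs_log2_ratio: float = 1.0,
) -> pd.DataFrame:
    """Flag clusters with disproportionate male/female nuclei.

    ``annotation`` carries a per-cell ``sex`` column in
    {female, male, mixed}; ``clusters`` the per-cell cluster label (same
    index).  Mixed cells are dropped first.  Returns one row per cluster
    containing at least one sexed cell, sorted by cluster id.
    """
    sex = annotation["sex"]
    labels = pd.Series(clusters).reindex(sex.index)
    keep = sex.isin(["female", "male"])
    sex, labels = sex[keep], labels[keep]
    n_f_total = int((sex == "female").sum())
    n_m_total = int((sex == "male").sum())
    if n_f_total == 0 or n_m_total == 0:
        raise ValueError("need at least one female-sample and one male-sample cell")
    q = n_m_total / (n_m_total + n_f_total)
    ratio = n_m_total / n_f_total

    rows = []
    for c in sorted(labels.dropna().unique()):
        in_c = labels == c
        n_f = int((sex[in_c] == "female").sum())
        n_m = int((sex[in_c] == "male").sum())
        n_f_norm = n_f * ratio
        n_m_norm = float(n_m)
        # raw male fraction: equals the input rate q for an unbiased cluster
        male_frac = n_m / (n_f + n_m) if (n_f + n_m) > 0 else q
        log2_ratio = np.log2((n_m_norm + 0.5) / (n_f_norm + 0.5))
        p = binom_test_two_sided(n_m, n_f + n_m, q)
        rows.append((c, n_f, n_m, n_f_norm, n_m_norm, male_frac, log2_ratio, p))

    table = pd.DataFrame(
        rows, columns=SEX_BIAS_COLUMNS[:8]
    )
    table["p_adj"] = bh_adjust(table["p_value"].to_numpy())
    significant = (table["p_adj"] < alpha) & (
        table["log2_ratio"].abs() >= min_abs_log2_ratio
    )
    direction = np.where(table["log2_ratio"] > 0, "male", "female")
    table["biased"] = np.where(significant, direction, "none")
    return table


@dataclass
class PseudobulkResult:
    """Aggregated counts / CPM per (cluster, sex) and per-gene sex DE stats."""

    counts: pd.DataFrame  # genes × MultiIndex(cluster, sex)
    cpm: pd.DataFrame
    stats: pd.DataFrame  # gene, mean_log2fc, p_value, p_adj


def pseudobulk_sex_de(
    matrix: CountMatrix,
    annotation: pd.DataFrame,
    clusters: pd.Series,
) -> PseudobulkResult:
    """Paired pseudobulk female-vs-male differential expression.

    Requires at least 2 clusters containing cells of both sexes (mixed
    excluded); raises otherwise.
    """
    sex = annotation["sex"].reindex(matrix.cell_ids)
    labels = pd.Series(clusters).reindex(matrix.cell_ids)
    sums = {}
    for c in sorted(labels.dropna().unique()):
        for s in ("female", "male"):
            mask = ((labels == c) & (sex == s)).to_numpy()
            if mask.any():
                sums[(c, s)] = np.asarray(matrix.X[mask].sum(axis=0)).ravel()
    counts = pd.DataFrame(sums, index=matrix.gene_ids)
    counts.columns = pd.MultiIndex.from_tuples(counts.columns, names=["cluster", "sex"])

    paired = [
        c
        for c in counts.columns.get_level_values("cluster").unique()
        if (c, "female") in counts.columns and (c, "male") in counts.columns
    ]
    if len(paired) < 2:
        raise ValueError(
            f"pseudobulk sex DE needs >= 2 clusters with both sexes, found {len(paired)}"
        )
    counts = counts[[(c, s) for c in paired for s in ("female", "male")]]
    totals = counts.sum(axis=0)
    cpm = counts / totals * 1e6

    lfc = np.stack(
        [
            np.log2((cpm[(c, "female")] + 1.0) / (cpm[(c, "male")] + 1.0))
            for c in paired
        ],
        axis=1,
    )  # genes × clusters
    mean_lfc = lfc.mean(axis=1)
    p = np.array([_signed_rank_p(row) for row in lfc])
    stats = pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "mean_log2fc": mean_lfc,
            "p_value": p,
            "p_adj": bh_adjust(p),
        }
    )
    return PseudobulkResult(counts=counts, cpm=cpm, stats=stats)


def _signed_rank_p(diffs: np.ndarray) -> float:
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        return 1.0
    return float(scipy.stats.wilcoxon(diffs, alternative="two-sided").pvalue)
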