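#!/usr/bin/env python
"""Neurotransmitter co-expression (UpSet counts), cluster-defining
neuropeptides, and TF-neuropeptide correlations.

A cell carries a neurotransmitter role when its marker gene (VGlut, VAChT,
Gad1, Tbh, ple, SerT, Tdc2) exceeds log-normalized expression 2; every
observed role combination is counted exactly.  Neuropeptides enriched in
1-5 clusters (significant positive markers) are reported as
cluster-defining, and each neuropeptide's five most correlated TFs across
all cells are listed.
"""

from _common import RESULTS, load_atlas, load_markers

from t2atlas.io import write_tables
from t2atlas.programs import (
    classify_neurotransmitters,
    coexpression_counts,
    select_cluster_defining_np,
    tf_np_correlation,
)

matrix, kept, norm, annotation, gene_ann, truth = load_atlas()
markers = load_markers()

profile = classify_neurotransmitters(norm, gene_ann)
upset = coexpression_counts(profile)
print("neurotransmitter combinations (top 8 of", len(upset), "):")
for _, row in upset.head(8).iterrows():
    print(f"  {row['combination']:<35s} {row['count']:>5d} ({row['percentage']:.1f}%)")
multi = upset[upset["combination"].str.contains("\\+")]["percentage"].sum()
print(f"cells co-expressing 2+ neurotransmitters: {multi:.1f}%")

np_map = select_cluster_defining_np(markers, gene_ann)
print(f"{len(np_map)} cluster-defining neuropeptides:")
for gene, cl in sorted(np_map.items()):
    print(f"  {gene}: clusters {cl}")

corr, top = tf_np_correlation(norm, gene_ann)
example = sorted(k for k, v in top.items() if v)[0]
print(f"top-5 TFs correlated with {example}: {top[example]}")

write_tables({"upset_counts": upset, "tf_np_corr": corr.reset_index()}, RESULTS)
print(f"wrote {RESULTS}/upset_counts.tsv and {RESULTS}/tf_np_corr.tsv")
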