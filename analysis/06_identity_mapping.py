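#!/usr/bin/env python
"""Map clusters to neuron-type identities four ways.

1. Pearson correlation against synthetic bulk reference profiles (assign by
   highest coefficient).  2. Split-Gal4 enhancer genes: clusters where every
   enhancer gene has positive scaled average expression.  3. Signed marker
   constraint queries.  4. Glial marker panels on repo+ clusters.
"""

import warnings

import pandas as pd
from _common import RESULTS, SEED, load_atlas, load_clusters

from t2atlas.identity import (
    annotate_by_marker_panel,
    assign_identity_by_max,
    cluster_mean_profiles,
    correlate_bulk,
    map_enhancer_genes,
    query_marker_constraints,
    select_marker_positive_clusters,
)
from t2atlas.io import write_tables
from t2atlas.qc import scaled_average_expression
from t2atlas.simulate import generate_bulk_reference

matrix, kept, norm, annotation, gene_ann, truth = load_atlas()
clusters = load_clusters()

# 1. bulk correlation against references built from three planted clusters
chosen = [3, 7, 12]
ref = generate_bulk_reference(norm, truth, chosen, noise_sd=0.1, seed=SEED + 3)
profiles = cluster_mean_profiles(norm, truth.cell_cluster.reindex(norm.cell_ids))
coef = correlate_bulk(profiles, ref)
assigned = assign_identity_by_max(coef).set_index("cluster")
hits = sum(assigned.loc[c, "neuron_type"] == truth.bulk_types[c] for c in chosen)
print(f"bulk correlation: {hits}/{len(chosen)} reference clusters recover their own type")

# 2. enhancer-gene mapping with a synthetic driver built from a planted program
scaled_avg = scaled_average_expression(norm, clusters)
np_cluster, np_genes = next(
    (c, g) for c, g in sorted(truth.planted_np.items()) if len(g) >= 2
)
drivers = pd.DataFrame(
    [{"driver_id": "SS_demo", "neuron_type": f"type_c{np_cluster}", "enhancer_genes": list(np_genes[:2])}]
)
candidates = map_enhancer_genes(scaled_avg, drivers)
print(
    f"driver SS_demo ({'+'.join(np_genes[:2])}, planted in truth cluster {np_cluster}): "
    f"candidate clusters {candidates['SS_demo']}"
)

# 3. marker-constraint query: cells of the same program, phrased as signs
tf_on = truth.planted_codes["homeodomain"].loc[np_cluster]
pos = [t for t, b in tf_on.items() if b == 1][:2]
neg = [t for t, b in tf_on.items() if b == 0][:1]
constraints = [(g, "+") for g in pos] + [(g, "-") for g in neg]
matches = query_marker_constraints(scaled_avg, constraints)
print(f"constraint query {constraints}: clusters {matches}")

# 4. glial subsetting + panel annotation
glial = select_marker_positive_clusters(norm, clusters, "repo")
panels = {
    s: list(gene_ann.index[gene_ann["glial_panel"] == s])
    for s in gene_ann["glial_panel"].unique()
    if s not in ("none", "pan_glial")
}
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    labels = annotate_by_marker_panel(scaled_avg.loc[glial], panels)
print(f"repo+ clusters {glial} annotated as {labels}")

write_tables({"assignments": assigned.reset_index()}, RESULTS)
print(f"wrote {RESULTS}/assignments.tsv")
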