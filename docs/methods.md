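# Methods

## The synthetic world

`t2atlas.simulate.generate_atlas` draws an atlas whose statistical structure
matches what the downstream analyses assume about T2-derived adult brain
snRNA-seq data.

**Counts.** Per-cell depth is lognormal with expected value `depth_mean`
(the lognormal location is mean-corrected: μ = ln(depth_mean) − σ²/2 with
σ = `depth_shape`, so the *mean* — not the median — equals `depth_mean`;
default 1,000 counts, σ = 0.35, roughly the shallow nuclear libraries of
split-pool protocols).  Given a cell's depth and its cluster/sex expression
program, counts are negative binomial in the mean / inverse-dispersion
parameterization, variance μ + μ²/θ, with θ = `dispersion` = 2 (moderate
overdispersion typical of UMI data).  At the default configuration the
matrix is ~72% sparse.

**Expression programs.** Relative gene weights are normalized per cell, so
only ratios matter.  Three regimes coexist deliberately:

- *Filler genes* span a lognormal baseline (σ = `baseline_logmean_sd` = 1)
  and carry no cluster signal.
- *TF genes* sit at a controlled moderate baseline (weight ≈ 2, mild
  spread) and are multiplied by 2^`de_log2fc` (default 2) in clusters where
  the planted code has a 1-bit.  Class sizes default to fly-like
  proportions (40 zinc finger, 25 helix-turn-helix, 30 homeodomain,
  12 basic domain, 15 unknown DBD, 8 HMG = 130 TFs); codes are Bernoulli
  with `code_density` = 0.3.  This keeps code recovery statistical: a
  single on-gene is not decisive, but ~40 of them are.
- *Identity genes* — the 7 NT markers, 13 neuropeptides, repo and the glial
  subtype panels — are near-silent off (weight 0.02) and multiplied by
  2^`marker_log2fc` (default 11) when on, mirroring the high dynamic range
  of real transporter / enzyme / neuropeptide genes on which thresholded
  classification rests.  Sex markers (yp1/2/3 + dsx female; lncRNA:roX1/2 +
  fru male) use a separate, moderate 2^`sex_effect_log2fc` (default 4):
  strong enough to dominate pseudobulk DE ranks, weak enough that clusters
  do not split by sex in the embedding — matching atlases in which sex is a
  within-cluster covariate, not a cluster boundary.

**Structure.** Cluster proportions default to uniform; `sex_bias_program`
clusters multiply their draw probability by 2^(±`sex_bias_log2fc`/2) per
hidden sex (default net 4× male:female enrichment).  Mixed samples draw
cells 50/50 from the female and male programs but are labeled
`sex="mixed"` and are excluded from all sex analyses, mirroring pooled
sorting rounds.  The last ~10% of clusters are glial: repo plus one subtype
panel on.  Transgene counts are drawn separately: each of FLP/GFP/RFP is
detected in a T2 cell with probability `transgene_rate` (0.8), with count
1 + Poisson(0.7) when detected; T1 cells are structurally zero — a hard
guarantee, not a statistical one.  Mitochondrial genes' share of expected
counts is pinned to `mito_rate_per_cell` (2%) after all program
multipliers, so the QC quantity is calibrated by construction.

**What the generator does not emulate:** ambient RNA, doublets, batch
chemistry, gene-length bias, or correlated gene modules beyond the planted
programs.  A green recovery test therefore establishes that the analysis
machinery is correct on data satisfying its own assumptions — not that the
thresholds are optimal for any particular real dataset.

## Analysis conventions

- **QC boundaries are inclusive** (cells removed for *fewer than* 200 /
  *more than* 2,500 genes or *more than* 5% mito), so 200, 2,500 and 5.0%
  survive.
- **Normalization**: natural log, pseudo-count 1, scale factor 10⁴
  (configurable).  **Scaling**: sample (n−1) SD; zero-variance genes map to
  0; clip at ±10.
- **HVG selection** ranks genes by dispersion z-scored within 20
  mean-expression bins.  It exists for a quantitative reason: with sparse
  cluster programs (~130 informative genes of 2,000), the between-cluster
  eigenvalues of the full scaled matrix fall below the Marchenko–Pastur
  noise edge at ~300 cells/cluster and PCA cannot see the structure;
  restricting to ~700 variable genes lifts the signal above the noise
  floor.  The recovery configuration (700 HVGs, 50 PCs, k = 15, Leiden
  resolution 4.0) came from a design-stage sweep of these method knobs;
  the generator itself was never adjusted against test outcomes.
- **Clustering** is Leiden (RB-configuration) on a shared-nearest-neighbor
  graph (Jaccard overlap of kNN sets, pruned below 1/15).  Resolution sets
  the community scale and must match it: ~0.5–1 for a handful of large
  blobs, 4 for 30 clusters of 300 cells, and the published large-atlas
  analyses used 12 at ~50k cells.  Modularity optimization will split a
  single large Gaussian blob at too-high resolution; that is a property of
  the objective, not a defect.
- **Markers**: Wilcoxon rank-sum, in-cluster vs all other cells, on
  log-normalized values after prefilters (detection ≥ 10% in-cluster,
  log2FC ≥ 0.25 computed on expm1-means with ε = 10⁻⁹); BH within cluster
  over tested genes.  When both groups have ≤ 8 observations the exact
  tie-aware null is computed by a subset-sum convolution over doubled
  midranks; otherwise a normal approximation with tie correction, no
  continuity correction.  Two-sided p-values are min(1, 2·min(lower,
  upper)) in both paths.  A signed mode shares the thresholds and also
  reports depleted genes.
- **NT classification** thresholds the *log-normalized* scale (the "none"
  class is defined there); a z-scored mode is available by config.  Role
  labels follow the atlas convention (Tbh → tyraminergic, Tdc2 →
  octopaminergic) even though the canonical enzyme-to-transmitter mapping
  differs.
- **Sex bias** combines a BH-adjusted exact binomial test (minimum-tail
  doubling) with |log2 ratio| ≥ 1 on 0.5-pseudo-counted input-normalized
  counts, because no single statistical criterion for "disproportionate"
  is canonical.  `male_fraction_norm` reports the raw male share, which
  equals the input rate q for an unbiased cluster.  Pseudobulk DE treats
  clusters as paired replicates (Wilcoxon signed-rank across clusters on
  per-cluster log2((CPM_f+1)/(CPM_m+1))); pseudo-count 1 for CPM ratios.
- **TF codes**: binarization uses significance only (p_adj < 0.05 on the
  positive-mode marker table); TFs marking no cluster remain as all-zero
  columns so the code dimension is the class size.  Both-empty code pairs
  have Jaccard 1 (identical codes must not look maximally dissimilar).
  Heatmap order is the optimal-leaf-ordered average-linkage dendrogram on
  1 − J.  Percent-unique is reported to one decimal.
- **Identity mapping**: plain Pearson on log-scale cluster means over the
  top-2,000 most variable genes (the published matching algorithm's
  internals are out of scope); assignment by per-cluster argmax, ties to
  the earlier reference (logged).  "Positive scaled average expression" is
  read literally as > 0 on the across-cluster z-scale, and the negative
  constraint as ≤ 0.  Glial panels label a cluster when ≥ 50% of panel
  genes are positive on that scale; overlapping labels join as "A/B".

## Numerical and degenerate-input choices

Zero-total cells yield pct_mito 0 with a warning at QC and are a named
error at normalization.  Zero-variance genes/vectors: scaled to 0 in
scaling; excluded from TF–NP ranking; NaN-flagged (never silently dropped)
in bulk correlation.  Empty marker tables produce all-zero codes and
header-only TSVs.  All randomness flows from one root seed through
`numpy.random.SeedSequence` spawns; per-stage seeds are recorded in the run
report.

## Known limitations

- Subtype panels whose genes are planted in no cluster get noise-driven
  positives under the literal "> 0 scaled average" rule; with several
  unplanted panels the glial annotation over-labels.  Real panels are
  expressed somewhere, so this is an artifact of sparse synthetic worlds.
- The pipeline concatenates samples; batch integration is out of scope, so
  batch effects, if simulated, would confound clustering.
- Published real-data counts (30,699 nuclei, 161 neuronal clusters, 21%
  cholinergic, 13 cluster-defining neuropeptides, specific cluster ids)
  require the deposited dataset and are not desk-reproducible; the tests
  instead verify the arithmetic that produced the printed percentages, one
  fixture at published scale (the 3,125 / 27,574 lineage split), and full
  parameter recovery on the synthetic atlas.
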