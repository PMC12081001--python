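#!/usr/bin/env python
"""Generate the synthetic T2 atlas used by every downstream analysis.

30 planted clusters (3 of them glial, 3 sex-biased), 9,000 nuclei across a
female, a male and a mixed sample, 2,000 genes with TF combinatorial codes,
neurotransmitter / neuropeptide programs, sex markers and transgene lineage
labels.  Writes the 10x-style bundle plus truth.json under results/atlas/.
"""

import warnings

from _common import ATLAS, SEED

from t2atlas.simulate import SimulationConfig, generate_atlas, save_atlas

cfg = SimulationConfig(
    samples=[("female_1", "female", 3000), ("male_1", "male", 3000), ("mixed_1", "mixed", 3000)],
    n_clusters=30,
    n_genes=2000,
    sex_bias_program={5: "male", 11: "female", 17: "male"},
    seed=SEED,
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    matrix, annotation, gene_ann, truth = generate_atlas(cfg)
save_atlas(matrix, annotation, gene_ann, truth, ATLAS)

sparsity = 1 - matrix.X.nnz / (matrix.n_cells * matrix.n_genes)
print(f"wrote {ATLAS}")
print(f"{matrix.n_cells} cells x {matrix.n_genes} genes, sparsity {sparsity:.1%}")
print(f"T2 fraction: {(truth.cell_lineage == 'T2').mean():.2f}")
print(f"glial clusters: {truth.glial_clusters}")
print(f"planted sex-biased clusters: {sorted(truth.planted_bias)}")
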