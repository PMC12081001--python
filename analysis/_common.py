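"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

import pandas as pd

from t2atlas.io import read_mtx_bundle, read_table
from t2atlas.qc import compute_cell_qc, filter_cells, log_normalize
from t2atlas.simulate import load_truth

RESULTS = Path(__file__).resolve().parent.parent / "results"
ATLAS = RESULTS / "atlas"
SEED = 2025


def load_atlas():
    """Bundle + truth written by 01_simulate_atlas.py, QC-filtered and normalized."""
    if not ATLAS.exists():
        raise SystemExit("run analysis/01_simulate_atlas.py first")
    matrix, gene_ann = read_mtx_bundle(ATLAS)
    annotation = pd.read_csv(ATLAS / "metadata.tsv", sep="\t", index_col="cell_id")
    truth = load_truth(ATLAS / "truth.json")
    qc = compute_cell_qc(matrix, gene_ann)
    kept = filter_cells(matrix, qc)
    norm = log_normalize(kept)
    return matrix, kept, norm, annotation.loc[kept.cell_ids], gene_ann, truth


def load_clusters():
    path = RESULTS / "clusters.tsv"
    if not path.exists():
        raise SystemExit("run analysis/02_qc_cluster_markers.py first")
    return read_table(path).set_index("cell_id")["cluster"]


def load_markers():
    path = RESULTS / "markers.tsv"
    if not path.exists():
        raise SystemExit("run analysis/02_qc_cluster_markers.py first")
    return read_table(path)
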