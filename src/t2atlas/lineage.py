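"""Transgene-based lineage assignment.

T2-neuroblast progeny are permanently lineage-traced: the FLP / GFP / RFP
transgene transcripts appear only in T2-derived nuclei.  A nucleus with at
least one UMI of any flagged transgene is called T2; triple-negative nuclei
are called T1.  Nuclear counts are sparse, so any UMI counts as evidence.
"""

from __future__ import annotations

import pandas as pd
import numpy as np

from .io import CountMatrix

__all__ = ["assign_lineage"]


def assign_lineage(matrix: CountMatrix, genes: pd.DataFrame) -> pd.Series:
    """Per-cell lineage label, ``"T2"`` iff any transgene count >= 1 else ``"T1"``."""
    flags = genes.reindex(matrix.gene_ids)["is_transgene"].to_numpy(dtype=bool)
    if not flags.any():
        raise ValueError("no transgene genes flagged in the annotation")
    positive = np.asarray((matrix.X[:, flags] > 0).sum(axis=1)).ravel() > 0
    return pd.Series(
        np.where(positive, "T2", "T1"),
        index=pd.Index(matrix.cell_ids, name="cell_id"),
        name="lineage",
    )
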