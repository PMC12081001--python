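"""Readers and writers for the formats the pipeline touches.

On disk the convention follows the 10x Genomics bundle: ``matrix.mtx`` in
Matrix Market coordinate format holding genes × cells with 1-based indices,
plus ``features.tsv`` (one gene per row) and ``barcodes.tsv`` (one cell per
row).  Internally every matrix is cells × genes; the transpose happens at the
boundary.  All tables are TSV with a header row, floats at 6 significant
digits, deterministic row order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "FormatError",
    "make_gene_annotation",
    "read_mtx_bundle",
    "write_mtx_bundle",
    "read_table",
    "write_tables",
    "TF_CLASSES",
    "NT_ROLE_OF_GENE",
    "NT_ROLES",
]

#: Structural transcription-factor classes used for combinatorial-code analysis.
TF_CLASSES = (
    "zinc_finger",
    "helix_turn_helix",
    "homeodomain",
    "basic_domain",
    "unknown_dbd",
    "hmg",
)

#: Fast-acting neurotransmitter marker gene -> role, labelled as in the source
#: atlas (Tbh is reported as the tyraminergic label and Tdc2 as octopaminergic).
NT_ROLE_OF_GENE = {
    "VGlut": "glutamatergic",
    "VAChT": "cholinergic",
    "Gad1": "GABAergic",
    "Tbh": "tyraminergic",
    "ple": "dopaminergic",
    "SerT": "serotonergic",
    "Tdc2": "octopaminergic",
}

#: The fixed 7-role universe, in marker-gene order.
NT_ROLES = tuple(NT_ROLE_OF_GENE.values())


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


@dataclass
class CountMatrix:
    """Sparse non-negative integer matrix of UMI counts, cells × genes."""

    X: sp.csr_matrix
    cell_ids: pd.Index
    gene_ids: pd.Index

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.cell_ids = pd.Index(self.cell_ids)
        self.gene_ids = pd.Index(self.gene_ids)
        n_cells, n_genes = self.X.shape
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise FormatError(
                f"axis lengths ({len(self.cell_ids)}, {len(self.gene_ids)}) "
                f"do not match matrix shape {self.X.shape}"
            )
        if self.cell_ids.has_duplicates:
            raise FormatError("duplicate cell ids")
        if self.gene_ids.has_duplicates:
            raise FormatError("duplicate gene ids")
        data = self.X.data
        if data.size:
            if np.any(data < 0):
                raise FormatError("negative count entries")
            if not np.allclose(data, np.round(data)):
                raise FormatError("non-integer count entries")
        self.X.data = np.asarray(np.round(data), dtype=np.int64)

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def subset_cells(self, mask_or_index) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(self.X[idx], self.cell_ids[idx], self.gene_ids)

    def subset_genes(self, mask_or_index) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(self.X[:, idx], self.cell_ids, self.gene_ids[idx])


def make_gene_annotation(
    gene_ids,
    symbols=None,
    is_mito=None,
    is_transgene=None,
    tf_class=None,
    nt_role=None,
    is_neuropeptide=None,
    glial_panel=None,
) -> pd.DataFrame:
    """Assemble a gene annotation table.

    Returns a DataFrame indexed by gene id with columns ``symbol``,
    ``is_mito``, ``is_transgene``, ``tf_class`` (one of :data:`TF_CLASSES` or
    ``"none"``), ``nt_role`` (one of the 7 roles or ``"none"``),
    ``is_neuropeptide`` and ``glial_panel`` (subtype label or ``"none"``).
    A gene may carry at most one tf_class and at most one nt_role.
    """
    idx = pd.Index(gene_ids, name="gene_id")
    n = len(idx)

    def as_series(values, default):
        if values is None:
            return pd.Series([default] * n, index=idx)
        s = pd.Series(values)
        if not s.index.equals(idx):
            s = s.reindex(idx, fill_value=default)
        return s

    ann = pd.DataFrame(
        {
            "symbol": as_series(symbols, None).fillna(pd.Series(idx, index=idx)),
            "is_mito": as_series(is_mito, False).astype(bool),
            "is_transgene": as_series(is_transgene, False).astype(bool),
            "tf_class": as_series(tf_class, "none"),
            "nt_role": as_series(nt_role, "none"),
            "is_neuropeptide": as_series(is_neuropeptide, False).astype(bool),
            "glial_panel": as_series(glial_panel, "none"),
        }
    )
    bad_class = set(ann["tf_class"]) - set(TF_CLASSES) - {"none"}
    if bad_class:
        raise ValueError(f"unknown tf_class values: {sorted(bad_class)}")
    bad_role = set(ann["nt_role"]) - set(NT_ROLES) - {"none"}
    if bad_role:
        raise ValueError(f"unknown nt_role values: {sorted(bad_role)}")
    return ann


# ---------------------------------------------------------------------------
# 10x-style bundle
# ---------------------------------------------------------------------------

def read_mtx_bundle(dir_path, orientation: str = "genes_by_cells"):
    """Read a ``matrix.mtx`` / ``features.tsv`` / ``barcodes.tsv`` bundle.

    Parameters
    ----------
    dir_path
        Directory holding the three files (``.gz`` variants of the matrix are
        accepted by :func:`scipy.io.mmread` transparently).
    orientation
        ``"genes_by_cells"`` (the on-disk 10x convention, default) or
        ``"cells_by_genes"``.  The returned matrix is always cells × genes.

    Returns
    -------
    (CountMatrix, GeneAnnotation or None)
        The annotation is read from ``genes.tsv``-style extra columns when
        present in ``features.tsv`` (columns beyond the first two are kept),
        otherwise ``None``.
    """
    dir_path = Path(dir_path)
    if orientation not in ("genes_by_cells", "cells_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    mtx_path = dir_path / "matrix.mtx"
    if not mtx_path.exists():
        mtx_path = dir_path / "matrix.mtx.gz"
    for name in ("features.tsv", "barcodes.tsv"):
        if not (dir_path / name).exists():
            raise FormatError(f"missing {name} in {dir_path}")
    if not mtx_path.exists():
        raise FormatError(f"missing matrix.mtx in {dir_path}")

    try:
        m = scipy.io.mmread(mtx_path)
    except ValueError as exc:
        raise FormatError(f"malformed matrix.mtx: {exc}") from exc
    m = sp.csr_matrix(m)
    if m.data.size and not np.allclose(m.data, np.round(m.data)):
        raise FormatError("matrix.mtx contains non-integer entries")

    features = pd.read_csv(dir_path / "features.tsv", sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(dir_path / "barcodes.tsv", sep="\t", header=None, dtype=str)
    gene_ids = pd.Index(features.iloc[:, 0])
    cell_ids = pd.Index(barcodes.iloc[:, 0])

    if orientation == "genes_by_cells":
        n_genes_disk, n_cells_disk = m.shape
        m = sp.csr_matrix(m.T)
    else:
        n_cells_disk, n_genes_disk = m.shape
    if n_genes_disk != len(gene_ids):
        raise FormatError(
            f"matrix header says {n_genes_disk} genes but features.tsv has {len(gene_ids)} rows"
        )
    if n_cells_disk != len(cell_ids):
        raise FormatError(
            f"matrix header says {n_cells_disk} cells but barcodes.tsv has {len(cell_ids)} rows"
        )

    annotation = None
    ann_path = dir_path / "gene_annotation.tsv"
    if ann_path.exists():
        annotation = read_gene_annotation(ann_path)
    return CountMatrix(m, cell_ids, gene_ids), annotation


def write_mtx_bundle(matrix: CountMatrix, dir_path, gene_annotation: pd.DataFrame | None = None) -> None:
    """Write a CountMatrix as a 10x-style bundle (genes × cells on disk)."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(dir_path / "matrix.mtx", sp.coo_matrix(matrix.X.T), field="integer")
    pd.Series(matrix.gene_ids).to_csv(dir_path / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(matrix.cell_ids).to_csv(dir_path / "barcodes.tsv", sep="\t", header=False, index=False)
    if gene_annotation is not None:
        write_gene_annotation(gene_annotation, dir_path / "gene_annotation.tsv")


def read_gene_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col="gene_id")
    for col in ("is_mito", "is_transgene", "is_neuropeptide"):
        ann[col] = ann[col].astype(bool)
    for col in ("tf_class", "nt_role", "glial_panel"):
        ann[col] = ann[col].fillna("none").astype(str)
    return ann


def write_gene_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------

def _format_float(x) -> str:
    if isinstance(x, (float, np.floating)):
        return f"{x:.6g}"
    return str(x)


def write_tables(objects: dict, dir_path) -> list:
    """Write named result tables as TSVs with deterministic formatting.

    ``objects`` maps file stem → pandas DataFrame.  Floats are written at 6
    significant digits; the row order of the frame is preserved (producers
    sort by cluster id then gene id).  Returns the list of written paths.
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    written = []
    for stem, frame in objects.items():
        path = dir_path / f"{stem}.tsv"
        out = frame.copy()
        for col in out.columns:
            if pd.api.types.is_float_dtype(out[col]):
                out[col] = out[col].map(_format_float)
        out.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_json(path):
    return json.loads(Path(path).read_text())
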