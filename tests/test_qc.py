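"""QC arithmetic, filtering boundaries, normalization and scaling math."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from t2atlas.io import CountMatrix, make_gene_annotation
from t2atlas.qc import (
    compute_cell_qc,
    filter_cells,
    log_normalize,
    scale_genes,
    scaled_average_expression,
    select_hvgs,
)
from tests.conftest import norm_from_dense


def _counts(dense, mito=()):
    dense = np.asarray(dense)
    n, g = dense.shape
    gene_ids = [f"g{j}" for j in range(g)]
    matrix = CountMatrix(sp.csr_matrix(dense), [f"c{i}" for i in range(n)], gene_ids)
    genes = make_gene_annotation(gene_ids, is_mito={f"g{j}": True for j in mito})
    return matrix, genes


class TestCellQC:
    def test_counted_genes_and_mito_percent(self, tiny_counts):
        matrix, genes = tiny_counts
        with pytest.warns(UserWarning, match="zero total"):
            qc = compute_cell_qc(matrix, genes)
        assert qc.loc["c0", "n_genes_detected"] == 2
        assert qc.loc["c0", "pct_mito"] == 25.0
        # degenerate all-zero cell
        assert qc.loc["c1", "n_genes_detected"] == 0
        assert qc.loc["c1", "pct_mito"] == 0.0

    def test_simdata_mito_rate_matches_config(self, small_atlas):
        matrix, _, gene_ann, _ = small_atlas
        qc = compute_cell_qc(matrix, gene_ann)
        # configured thinning rate is 2%; sampling error at 1,200 cells is small
        assert abs(qc["pct_mito"].mean() - 2.0) < 0.5


class TestFilterCells:
    def test_paper_boundaries_inclusive(self):
        # cells detecting {150, 200, 2500, 2600} genes -> keep exactly {200, 2500}
        n_genes = 2600
        rows = []
        for k in (150, 200, 2500, 2600):
            row = np.zeros(n_genes)
            row[:k] = 1
            rows.append(row)
        matrix, genes = _counts(rows)
        qc = compute_cell_qc(matrix, genes)
        kept = filter_cells(matrix, qc)
        assert kept.cell_ids.tolist() == ["c1", "c2"]

    def test_mito_boundary_5pct_kept(self):
        dense = np.ones((1, 400))
        dense[0, 0] = 21  # mito gene holds 21 of 420 counts = exactly 5.0%
        matrix, genes = _counts(dense, mito=(0,))
        qc = compute_cell_qc(matrix, genes)
        assert qc["pct_mito"].iloc[0] == pytest.approx(5.0)
        assert filter_cells(matrix, qc).n_cells == 1

    def test_matches_brute_force_predicate(self):
        rng = np.random.default_rng(0)
        dense = rng.integers(0, 3, size=(10, 300))
        dense[0] = 0  # degenerate
        dense[3, :250] = 1
        matrix, genes = _counts(dense, mito=(0, 1, 2))
        with pytest.warns(UserWarning):
            qc = compute_cell_qc(matrix, genes)
        kept = filter_cells(matrix, qc, min_genes=100, max_genes=200, max_pct_mito=2.0)
        survivors = []
        for i in range(10):
            row = dense[i]
            n_det = (row > 0).sum()
            pct = 100 * row[:3].sum() / row.sum() if row.sum() else 0.0
            if 100 <= n_det <= 200 and pct <= 2.0:
                survivors.append(f"c{i}")
        assert kept.cell_ids.tolist() == survivors

    def test_idempotent(self, small_atlas):
        matrix, _, gene_ann, _ = small_atlas
        qc = compute_cell_qc(matrix, gene_ann)
        once = filter_cells(matrix, qc)
        qc2 = compute_cell_qc(once, gene_ann)
        twice = filter_cells(once, qc2)
        assert once.cell_ids.equals(twice.cell_ids)


class TestLogNormalize:
    def test_formula(self):
        matrix, _ = _counts([[10, 0]])
        norm = log_normalize(matrix)
        # count 10 of total 10 -> ln(1 + 10 * 1e4 / 10) = ln(10001)
        assert norm.X[0, 0] == pytest.approx(np.log(10001), abs=1e-9)
        assert norm.X[0, 1] == 0.0

    def test_depth_invariance(self):
        a, _ = _counts([[3, 7, 0]])
        b, _ = _counts([[6, 14, 0]])
        na, nb = log_normalize(a), log_normalize(b)
        np.testing.assert_allclose(na.X.todense(), nb.X.todense())

    def test_zero_total_cell_named_in_error(self):
        matrix, _ = _counts([[1, 1], [0, 0]])
        with pytest.raises(ValueError, match="c1"):
            log_normalize(matrix)

    def test_monotone_within_cell(self):
        matrix, _ = _counts([[1, 2, 5, 0]])
        vals = np.asarray(log_normalize(matrix).X.todense()).ravel()
        assert vals[3] < vals[0] < vals[1] < vals[2]


class TestScaleGenes:
    def test_two_cell_sample_sd_convention(self):
        norm = norm_from_dense([[0.0], [2.0]])
        scaled = scale_genes(norm)
        # sample sd of {0, 2} is sqrt(2): z = ±1/sqrt(2)
        np.testing.assert_allclose(scaled.ravel(), [-0.70710678, 0.70710678])

    def test_constant_gene_zero_and_clip(self):
        norm = norm_from_dense([[5.0, 0.0], [5.0, 0.0], [5.0, 1e6]])
        scaled = scale_genes(norm)
        assert (scaled[:, 0] == 0).all()
        assert scaled[2, 1] <= 10.0


class TestScaledAverageExpression:
    def test_matches_two_step_computation(self):
        norm = norm_from_dense([[1.0, 4.0], [1.0, 4.0], [2.0, 0.0], [6.0, 2.0]])
        clusters = pd.Series([0, 0, 1, 2], index=norm.cell_ids)
        out = scaled_average_expression(norm, clusters)
        means = np.array([[1.0, 4.0], [2.0, 0.0], [6.0, 2.0]])
        expected = (means - means.mean(0)) / means.std(0, ddof=1)
        np.testing.assert_allclose(out.to_numpy(), expected, atol=1e-12)

    def test_single_cluster_all_zero(self):
        norm = norm_from_dense([[1.0, 2.0], [3.0, 4.0]])
        clusters = pd.Series([0, 0], index=norm.cell_ids)
        out = scaled_average_expression(norm, clusters)
        assert (out.to_numpy() == 0).all()

    def test_per_gene_mean_zero_sd_unit_or_zero(self, small_norm, small_atlas):
        *_, truth = small_atlas
        out = scaled_average_expression(small_norm, truth.cell_cluster)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-9)
        sd = out.std(axis=0, ddof=1)
        assert np.all((np.abs(sd - 1) < 1e-9) | (sd < 1e-9))


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=10, deadline=None)
def test_filter_is_idempotent_property(seed):
    rng = np.random.default_rng(seed)
    dense = rng.poisson(0.8, size=(12, 250))
    matrix, genes = _counts(dense, mito=(0,))
    import warnings as w

    with w.catch_warnings():
        w.simplefilter("ignore")
        qc = compute_cell_qc(matrix, genes)
        once = filter_cells(matrix, qc, min_genes=50, max_genes=220, max_pct_mito=3.0)
        twice = filter_cells(
            once, compute_cell_qc(once, genes), min_genes=50, max_genes=220, max_pct_mito=3.0
        )
    assert once.cell_ids.equals(twice.cell_ids)


def test_select_hvgs_prefers_structured_genes(small_atlas, small_norm):
    *_, truth = small_atlas
    idx = select_hvgs(small_norm, n_top=120)
    chosen = set(np.array(small_norm.gene_ids)[idx])
    tf_chosen = sum(1 for g in chosen if g.startswith("tf_"))
    assert tf_chosen >= 60  # program genes dominate the variable set
    assert select_hvgs(small_norm, n_top=0).size == small_norm.n_genes
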