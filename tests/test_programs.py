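"""Neurotransmitter classification / UpSet counts, NP selection, TF–NP correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t2atlas.io import NT_ROLES, make_gene_annotation
from t2atlas.programs import (
    classify_neurotransmitters,
    coexpression_counts,
    select_cluster_defining_np,
    tf_np_correlation,
)
from t2atlas.qc import log_normalize
from tests.conftest import norm_from_dense

NT_GENE_IDS = ["VGlut", "VAChT", "Gad1", "Tbh", "ple", "SerT", "Tdc2"]


def _nt_norm(values):
    """values: cells × 7 array of log-normalized NT marker expression."""
    norm = norm_from_dense(values, gene_ids=NT_GENE_IDS)
    genes = make_gene_annotation(
        NT_GENE_IDS,
        nt_role=dict(zip(NT_GENE_IDS, NT_ROLES)),
    )
    return norm, genes


class TestClassify:
    def test_threshold_rule(self):
        vals = np.zeros((2, 7))
        vals[0, 1] = 2.5  # VAChT above threshold
        norm, genes = _nt_norm(vals)
        profile = classify_neurotransmitters(norm, genes)
        assert profile.loc["c0"].sum() == 1 and profile.loc["c0", "cholinergic"]
        assert profile.loc["c1"].sum() == 0

    def test_missing_marker_gene_named(self):
        norm = norm_from_dense(np.zeros((2, 6)), gene_ids=NT_GENE_IDS[:6])
        genes = make_gene_annotation(
            NT_GENE_IDS[:6], nt_role=dict(zip(NT_GENE_IDS[:6], NT_ROLES[:6]))
        )
        with pytest.raises(ValueError, match="octopaminergic"):
            classify_neurotransmitters(norm, genes)

    def test_planted_role_fractions_recovered(self, small_atlas, small_norm):
        _, _, gene_ann, truth = small_atlas
        profile = classify_neurotransmitters(small_norm, gene_ann)
        planted_roles = truth.cell_cluster.map(truth.planted_nt)
        role_of = dict(zip(NT_GENE_IDS, NT_ROLES))
        for gene, role in role_of.items():
            planted_frac = planted_roles.map(lambda s: gene in s).mean()
            observed_frac = profile[role].mean()
            assert abs(observed_frac - planted_frac) < 0.02

    @given(st.floats(min_value=0.5, max_value=5.0), st.floats(min_value=0.0, max_value=3.0))
    @settings(max_examples=20, deadline=None)
    def test_raising_threshold_shrinks_role_sets(self, t_low, delta):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 6, size=(30, 7))
        norm, genes = _nt_norm(vals)
        low = classify_neurotransmitters(norm, genes, threshold=t_low)
        high = classify_neurotransmitters(norm, genes, threshold=t_low + delta)
        assert ((high.to_numpy() <= low.to_numpy())).all()


class TestCoexpressionCounts:
    def test_hand_counted_combinations(self):
        vals = np.zeros((4, 7))
        vals[0, 1] = 3.0                     # ACh
        vals[1, 1] = 3.0                     # ACh
        vals[3, 0] = 3.0; vals[3, 2] = 3.0   # Glu + GABA
        norm, genes = _nt_norm(vals)
        table = coexpression_counts(classify_neurotransmitters(norm, genes))
        by = table.set_index("combination")
        assert by.loc["cholinergic", "count"] == 2
        assert by.loc["cholinergic", "percentage"] == 50.0
        assert by.loc["none", "count"] == 1
        # combination labels join roles in the fixed marker-gene order
        assert by.loc["glutamatergic+GABAergic", "count"] == 1

    def test_all_empty(self):
        norm, genes = _nt_norm(np.zeros((5, 7)))
        table = coexpression_counts(classify_neurotransmitters(norm, genes))
        assert table["combination"].tolist() == ["none"]
        assert table["percentage"].iloc[0] == 100.0

    def test_counts_and_percentages_conserved(self, small_atlas, small_norm):
        _, _, gene_ann, _ = small_atlas
        profile = classify_neurotransmitters(small_norm, gene_ann)
        table = coexpression_counts(profile)
        assert table["count"].sum() == len(profile)
        assert table["percentage"].sum() == pytest.approx(100.0, abs=0.01)


class TestClusterDefiningNP:
    def _markers(self, np_clusters):
        rows = []
        for c in np_clusters:
            rows.append({"cluster": c, "gene": "Ms", "log2fc": 2.0, "pct_in": 1.0,
                         "pct_out": 0.0, "p_value": 1e-6, "p_adj": 1e-5})
        rows.append({"cluster": 0, "gene": "gene0001", "log2fc": 3.0, "pct_in": 1.0,
                     "pct_out": 0.0, "p_value": 1e-9, "p_adj": 1e-8})
        return pd.DataFrame(rows)

    def _genes(self):
        return make_gene_annotation(["Ms", "gene0001"], is_neuropeptide={"Ms": True})

    def test_two_cluster_np_included(self):
        out = select_cluster_defining_np(self._markers([3, 9]), self._genes())
        assert out == {"Ms": [3, 9]}

    def test_zero_and_overspread_excluded(self):
        assert select_cluster_defining_np(self._markers([]), self._genes()) == {}
        out = select_cluster_defining_np(
            self._markers([1, 2, 3, 4, 5, 6]), self._genes(), max_clusters=5
        )
        assert out == {}

    def test_planted_np_programs_recovered(self, small_atlas, small_norm):
        from t2atlas.markers import rank_markers

        _, _, gene_ann, truth = small_atlas
        table = rank_markers(small_norm, truth.cell_cluster)
        out = select_cluster_defining_np(table, gene_ann)
        planted = {}
        for c, nps in truth.planted_np.items():
            for g in nps:
                planted.setdefault(g, []).append(c)
        planted = {g: sorted(cs) for g, cs in planted.items() if 1 <= len(cs) <= 5}
        assert out == planted


class TestTFNPCorrelation:
    def _inputs(self, np_vec, tf_vecs):
        genes = ["NP1"] + [f"TF{i}" for i in range(len(tf_vecs))]
        dense = np.column_stack([np_vec] + tf_vecs)
        norm = norm_from_dense(dense, gene_ids=genes)
        ann = make_gene_annotation(
            genes,
            is_neuropeptide={"NP1": True},
            tf_class={f"TF{i}": "homeodomain" for i in range(len(tf_vecs))},
        )
        return norm, ann

    def test_direct_covariance_formula(self):
        np_vec = [0.0, 1.0, 2.0, 3.0]
        tf_vec = [1.0, 2.0, 4.0, 4.0]
        norm, ann = self._inputs(np_vec, [tf_vec])
        corr, _ = tf_np_correlation(norm, ann)
        x, y = np.asarray(np_vec), np.asarray(tf_vec)
        expected = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
        )
        assert corr.loc["NP1", "TF0"] == pytest.approx(expected, abs=1e-12)

    def test_identical_vector_ranks_first_constant_excluded(self):
        np_vec = [0.0, 1.0, 2.0, 3.0]
        norm, ann = self._inputs(np_vec, [list(np_vec), [2.0, 2.0, 2.0, 2.0]])
        corr, top = tf_np_correlation(norm, ann)
        assert corr.loc["NP1", "TF0"] == pytest.approx(1.0)
        assert top["NP1"][0] == "TF0"
        assert "TF1" not in top["NP1"]

    def test_zero_variance_np_flagged(self):
        norm, ann = self._inputs([1.0, 1.0, 1.0, 1.0], [[0.0, 1.0, 2.0, 3.0]])
        corr, top = tf_np_correlation(norm, ann)
        assert np.isnan(corr.loc["NP1", "TF0"])
        assert top["NP1"] is None

    def test_symmetric_in_vector_roles(self):
        rng = np.random.default_rng(5)
        a, b = rng.uniform(0, 4, size=12), rng.uniform(0, 4, size=12)
        norm1, ann1 = self._inputs(a.tolist(), [b.tolist()])
        norm2, ann2 = self._inputs(b.tolist(), [a.tolist()])
        c1, _ = tf_np_correlation(norm1, ann1)
        c2, _ = tf_np_correlation(norm2, ann2)
        assert c1.loc["NP1", "TF0"] == pytest.approx(c2.loc["NP1", "TF0"], abs=1e-12)
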