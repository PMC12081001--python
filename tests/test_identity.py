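"""Cluster identity mapping: bulk correlation, enhancer genes, marker queries,
glial panels."""

import numpy as np
import pandas as pd
import pytest

from t2atlas.identity import (
    BulkReference,
    annotate_by_marker_panel,
    assign_identity_by_max,
    correlate_bulk,
    map_enhancer_genes,
    query_marker_constraints,
    select_marker_positive_clusters,
)
from t2atlas.qc import scaled_average_expression
from t2atlas.simulate import generate_bulk_reference
from tests.conftest import norm_from_dense


def _profiles(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=range(values.shape[0]), columns=genes)


class TestCorrelateBulk:
    def test_direct_covariance_formula(self):
        clusters = _profiles([[0, 1, 2, 3], [3, 1, 0, 2], [1, 1, 2, 0]])
        refs = BulkReference(_profiles([[1, 2, 4, 4], [2, 0, 1, 1]]).rename(
            index={0: "typeA", 1: "typeB"}))
        out = correlate_bulk(clusters, refs, gene_subset=list(clusters.columns))
        for c in range(3):
            for t, name in enumerate(["typeA", "typeB"]):
                expected = np.corrcoef(clusters.iloc[c], refs.profiles.iloc[t])[0, 1]
                assert out.iloc[c][name] == pytest.approx(expected, abs=1e-12)

    def test_reference_equal_to_cluster_mean_gives_r1(self):
        clusters = _profiles([[0, 1, 2, 3], [5, 0, 1, 1]])
        refs = BulkReference(clusters.iloc[[0]].rename(index={0: "self"}))
        out = correlate_bulk(clusters, refs, gene_subset=list(clusters.columns))
        assert out.loc[0, "self"] == pytest.approx(1.0)

    def test_constant_reference_flagged_undefined(self):
        clusters = _profiles([[0, 1, 2, 3], [5, 0, 1, 1]])
        refs = BulkReference(_profiles([[2, 2, 2, 2]]).rename(index={0: "flat"}))
        out = correlate_bulk(clusters, refs, gene_subset=list(clusters.columns))
        assert out["flat"].isna().all()

    def test_too_few_shared_genes_is_error(self):
        clusters = _profiles([[0, 1], [1, 0]])
        refs = BulkReference(_profiles([[1, 0]]).rename(index={0: "t"}))
        with pytest.raises(ValueError, match="shared genes"):
            correlate_bulk(clusters, refs, gene_subset=["g0", "g1"])


class TestAssignByMax:
    def test_planted_maxima_recovered_exactly(self):
        rng = np.random.default_rng(0)
        coef = pd.DataFrame(rng.uniform(-0.5, 0.5, size=(6, 3)),
                            columns=["tA", "tB", "tC"])
        planted = ["tB", "tA", "tC", "tA", "tB", "tC"]
        for c, t in enumerate(planted):
            coef.loc[c, t] = 0.9
        out = assign_identity_by_max(coef)
        assert out["neuron_type"].tolist() == planted

    def test_tie_goes_to_first_reference(self):
        coef = pd.DataFrame([[0.5, 0.5]], columns=["first", "second"])
        with pytest.warns(UserWarning, match="tie"):
            out = assign_identity_by_max(coef)
        assert out["neuron_type"].iloc[0] == "first"

    def test_all_undefined_row_unassigned(self):
        coef = pd.DataFrame([[np.nan, np.nan]], columns=["a", "b"])
        with pytest.warns(UserWarning, match="unassigned"):
            out = assign_identity_by_max(coef)
        assert out["neuron_type"].iloc[0] is None

    def test_recovery_from_synthetic_bulk(self, small_atlas, small_norm):
        from t2atlas.identity import cluster_mean_profiles

        *_, truth = small_atlas
        chosen = [1, 4, 6]
        correct = 0
        for seed in range(20):
            ref = generate_bulk_reference(small_norm, truth, chosen, noise_sd=0.1, seed=seed)
            profiles = cluster_mean_profiles(small_norm, truth.cell_cluster)
            out = assign_identity_by_max(correlate_bulk(profiles, ref)).set_index("cluster")
            if all(out.loc[c, "neuron_type"] == truth.bulk_types[c] for c in chosen):
                correct += 1
        assert correct == 20


class TestEnhancerGenes:
    def _scaled(self):
        return _profiles(
            [[0.5, -1.0, 2.0], [1.5, 0.3, -0.2], [2.0, 0.1, 0.4]],
            genes=["wnt10", "lmpt", "other"],
        )

    def _drivers(self, genes):
        return pd.DataFrame(
            [{"driver_id": "SS65380", "neuron_type": "FB2A", "enhancer_genes": genes}]
        )

    def test_all_genes_positive_required(self):
        out = map_enhancer_genes(self._scaled(), self._drivers(["wnt10", "lmpt"]))
        # ranked by descending min scaled average over the driver's genes
        assert out["SS65380"] == [1, 2]

    def test_no_candidate_empty(self):
        scaled = _profiles([[1.0, -1.0], [-1.0, 1.0]], genes=["wnt10", "lmpt"])
        out = map_enhancer_genes(scaled, self._drivers(["wnt10", "lmpt"]))
        assert out["SS65380"] == []

    def test_absent_gene_skips_driver(self):
        with pytest.warns(UserWarning, match="absent"):
            out = map_enhancer_genes(self._scaled(), self._drivers(["nope"]))
        assert out == {}

    def test_adding_gene_never_enlarges_candidates(self):
        scaled = self._scaled()
        one = map_enhancer_genes(scaled, self._drivers(["wnt10"]))["SS65380"]
        two = map_enhancer_genes(scaled, self._drivers(["wnt10", "lmpt"]))["SS65380"]
        assert set(two) <= set(one)


class TestMarkerQueries:
    def _scaled(self):
        # clusters 66 and 130 alone are Toy- Runt+ Ggamma30A+
        return pd.DataFrame(
            {
                "toy": [1.0, -0.5, -0.2, 0.8, -1.0],
                "runt": [0.5, 0.7, 1.2, -0.3, 0.9],
                "Ggamma30A": [0.2, 0.4, 0.9, 0.1, -0.6],
            },
            index=[10, 66, 130, 7, 42],
        )

    def test_signed_query(self):
        out = query_marker_constraints(
            self._scaled(), [("toy", "-"), ("runt", "+")], driver_genes=["Ggamma30A"]
        )
        assert out == [66, 130]

    def test_contradictory_constraints_empty(self):
        with pytest.warns(UserWarning, match="contradictory"):
            out = query_marker_constraints(self._scaled(), [("toy", "+"), ("toy", "-")])
        assert out == []

    def test_matches_brute_force_predicate(self):
        rng = np.random.default_rng(7)
        scaled = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("abcd"))
        constraints = [("a", "+"), ("c", "-")]
        out = query_marker_constraints(scaled, constraints)
        expected = [
            c for c in scaled.index
            if scaled.loc[c, "a"] > 0 and scaled.loc[c, "c"] <= 0
        ]
        assert out == expected

    def test_empty_constraints_warn_and_return_all(self):
        with pytest.warns(UserWarning, match="every cluster"):
            out = query_marker_constraints(self._scaled(), [])
        assert out == sorted(self._scaled().index)


class TestGlialSelection:
    def test_broadly_expressing_cluster_selected(self):
        dense = np.zeros((20, 2))
        dense[:10, 0] = 2.0          # cluster 0: repo in 100% at mean 2
        dense[10:12, 0] = 0.5        # cluster 1: repo in 20% of cells
        norm = norm_from_dense(dense, gene_ids=["repo", "other"])
        clusters = pd.Series([0] * 10 + [1] * 10, index=norm.cell_ids)
        out = select_marker_positive_clusters(norm, clusters, "repo")
        assert out == [0]

    def test_planted_glial_clusters_recovered(self, small_atlas, small_norm):
        *_, truth = small_atlas
        out = select_marker_positive_clusters(
            small_norm, truth.cell_cluster, "repo"
        )
        assert out == truth.glial_clusters

    def test_subset_conserves_cell_count(self, small_atlas, small_norm):
        *_, truth = small_atlas
        glial = select_marker_positive_clusters(small_norm, truth.cell_cluster, "repo")
        subset = truth.cell_cluster.isin(glial)
        assert subset.sum() == sum(
            (truth.cell_cluster == c).sum() for c in glial
        )


class TestMarkerPanels:
    def _scaled(self):
        return pd.DataFrame(
            {
                "alrm": [1.0, 0.5, -1.0],
                "Gat": [0.8, 0.6, -0.5],
                "zyd": [-0.5, 0.7, -0.2],
                "trol": [-0.1, 0.9, -0.3],
            },
            index=[0, 1, 2],
        )

    PANELS = {"astrocyte": ["alrm", "Gat"], "ensheathing": ["zyd", "trol"]}

    def test_single_and_overlapping_identities(self):
        out = annotate_by_marker_panel(self._scaled(), self.PANELS)
        assert out[0] == "astrocyte"
        assert out[1] == "astrocyte/ensheathing"
        assert out[2] == "unannotated"

    def test_absent_panel_gene_dropped_with_warning(self):
        panels = {"astrocyte": ["alrm", "not_here"]}
        with pytest.warns(UserWarning, match="absent"):
            out = annotate_by_marker_panel(self._scaled(), panels)
        assert out[0] == "astrocyte"
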