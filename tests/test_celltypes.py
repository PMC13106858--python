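"""Filtering, Pearson residuals, clustering, scoring, and annotation."""
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, roc_auc_score

import plaqueniche as pn


def _matrix(counts, genes=None):
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    cells = pd.DataFrame(
        {"cell_id": [f"c{i}" for i in range(n)], "x": np.zeros(n), "y": np.zeros(n)}
    )
    genes = genes or [f"g{j}" for j in range(counts.shape[1])]
    return pn.CellMatrix(counts, genes, cells)


class TestFilterMatrix:
    def test_gene_with_many_missing_dropped(self):
        counts = np.full((5, 3), 10.0)
        counts[0:3, 2] = np.nan  # gene C missing in 3 of 5 cells
        cm = pn.filter_matrix(_matrix(counts), max_missing_per_gene=3, min_counts_per_cell=1)
        assert cm.genes == ["g0", "g1"]
        assert cm.n_cells == 5

    def test_min_count_boundary_is_inclusive(self):
        counts = np.array([[19.0, 0.0], [20.0, 0.0], [25.0, 5.0]])
        cm = pn.filter_matrix(_matrix(counts), max_missing_per_gene=10, min_counts_per_cell=20)
        # total 19 dropped; total exactly 20 kept
        assert cm.n_cells == 2
        assert cm.counts[0, 0] == 20.0

    def test_identity_when_nothing_to_filter(self):
        counts = np.full((4, 3), 30.0)
        cm = pn.filter_matrix(_matrix(counts))
        assert np.array_equal(cm.counts, counts)

    def test_remaining_missing_imputed_to_zero(self):
        counts = np.full((5, 2), 30.0)
        counts[0, 1] = np.nan
        cm = pn.filter_matrix(_matrix(counts), max_missing_per_gene=3, min_counts_per_cell=1)
        assert cm.counts[0, 1] == 0.0

    def test_conservation_of_cells_and_genes(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, (50, 8)).astype(float)
        counts[rng.random((50, 8)) < 0.1] = np.nan
        raw = _matrix(counts)
        cm = pn.filter_matrix(raw, max_missing_per_gene=10, min_counts_per_cell=20)
        assert cm.n_genes + (raw.n_genes - cm.n_genes) == raw.n_genes
        assert 0 < cm.n_cells <= raw.n_cells

    def test_everything_filtered_is_error(self):
        counts = np.full((3, 2), 1.0)
        with pytest.raises(ValueError, match="min_counts_per_cell"):
            pn.filter_matrix(_matrix(counts), min_counts_per_cell=100)


class TestPearsonResiduals:
    def test_rank_one_matrix_gives_zero_residuals(self):
        a = np.array([1, 2, 3])[:, None]
        b = np.array([2, 1, 4, 3])[None, :]
        norm = pn.pearson_residuals(a * b)
        assert np.allclose(norm.residuals, 0.0, atol=1e-12)

    def test_hand_computed_two_by_two(self):
        norm = pn.pearson_residuals(np.array([[2, 0], [0, 2]]), theta=100)
        expect = 1.0 / np.sqrt(1.01)
        assert np.allclose(np.abs(norm.residuals), expect, atol=1e-5)
        assert norm.residuals[0, 0] > 0 > norm.residuals[0, 1]

    def test_large_theta_recovers_poisson_residuals(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(5, (20, 10)) + 1
        norm = pn.pearson_residuals(x, theta=1e9, clip=np.inf)
        row = x.sum(1, keepdims=True)
        col = x.sum(0, keepdims=True)
        mu = row @ col / x.sum()
        assert np.allclose(norm.residuals, (x - mu) / np.sqrt(mu), atol=1e-6)

    def test_clipping_bound_respected(self):
        x = np.eye(9, dtype=int) * 1000 + 1
        norm = pn.pearson_residuals(x)
        assert np.abs(norm.residuals).max() <= np.sqrt(9) + 1e-12

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        x = rng.poisson(4, (12, 7)) + 1
        norm = pn.pearson_residuals(x)
        pr = rng.permutation(12)
        pc = rng.permutation(7)
        permuted = pn.pearson_residuals(x[pr][:, pc])
        assert np.allclose(permuted.residuals, norm.residuals[pr][:, pc])

    def test_all_zero_column_is_error(self):
        x = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="columns"):
            pn.pearson_residuals(x)

    def test_matches_scanpy_implementation(self):
        anndata = pytest.importorskip("anndata")
        scanpy = pytest.importorskip("scanpy")
        rng = np.random.default_rng(3)
        x = rng.poisson(3, (40, 15)).astype(float) + 1
        ad = anndata.AnnData(x.copy())
        scanpy.experimental.pp.normalize_pearson_residuals(ad, theta=100)
        ours = pn.pearson_residuals(x, theta=100)
        assert np.allclose(ad.X, ours.residuals, atol=1e-8)


class TestClustering:
    def test_two_planted_types_recovered(self, small_field, two_type_spec):
        panel, types = two_type_spec
        cm, labels = pn.make_cells(types, 200, panel, small_field, seed=1)
        norm = pn.pearson_residuals(cm.counts, cm.genes)
        cl = pn.reduce_and_cluster(norm, seed=1)
        assert len(np.unique(cl)) == 2
        assert adjusted_rand_score(labels, cl) > 0.9

    def test_duplicating_cells_preserves_partition(self, small_field, two_type_spec):
        panel, types = two_type_spec
        cm, _ = pn.make_cells(types, 100, panel, small_field, seed=2)
        norm = pn.pearson_residuals(cm.counts, cm.genes)
        base = pn.reduce_and_cluster(norm, seed=2)
        dup = pn.reduce_and_cluster(
            pn.pearson_residuals(np.vstack([cm.counts, cm.counts]), cm.genes), seed=2
        )
        assert adjusted_rand_score(base, dup[: len(base)]) == pytest.approx(1.0)
        assert adjusted_rand_score(dup[: len(base)], dup[len(base):]) == pytest.approx(1.0)

    def test_single_type_yields_one_cluster(self, small_field):
        panel = [f"g{i}" for i in range(20)]
        one = [pn.CellTypeSpec("t", tuple(panel[:5]))]
        hits = 0
        for seed in range(20):
            cm, _ = pn.make_cells(one, 200, panel, small_field, seed=seed)
            cl = pn.reduce_and_cluster(pn.pearson_residuals(cm.counts), seed=seed)
            hits += len(np.unique(cl)) == 1
        assert hits >= 18

    def test_too_few_cells_is_error(self):
        with pytest.raises(ValueError, match="cells"):
            pn.reduce_and_cluster(np.random.default_rng(0).normal(size=(10, 5)))


class TestScoreGeneSet:
    def test_constant_matrix_scores_zero(self):
        genes = [f"g{i}" for i in range(20)]
        score = pn.score_gene_set(np.full((30, 20), 3.0), genes, genes[:5])
        assert np.allclose(score, 0.0)

    def test_whole_panel_scores_near_zero(self, small_field, two_type_spec):
        panel, types = two_type_spec
        worst = 0.0
        for seed in range(10):
            cm, _ = pn.make_cells(types, 50, panel, small_field, seed=seed)
            norm = pn.pearson_residuals(cm.counts, cm.genes)
            score = pn.score_gene_set(norm.residuals, cm.genes, panel, seed=seed)
            worst = max(worst, np.abs(score.mean()))
        assert worst <= 0.05

    def test_planted_high_cells_separate_with_auroc(self, small_field, two_type_spec):
        panel, types = two_type_spec
        cm, labels = pn.make_cells(types, 200, panel, small_field, seed=4)
        norm = pn.pearson_residuals(cm.counts, cm.genes)
        score = pn.score_gene_set(norm.residuals, cm.genes, list(types[0].marker_genes), seed=4)
        assert roc_auc_score(labels == "tcell", score) > 0.95

    def test_disjoint_set_is_error(self):
        with pytest.raises(ValueError, match="panel"):
            pn.score_gene_set(np.ones((5, 4)), ["a", "b", "c", "d"], ["zzz"])


class TestAnnotation:
    def test_hand_computed_separation_score(self):
        scores = np.array([1.0, 1.2, 0.8, 0.0, 0.1, -0.1, 0.0])
        member = np.array([True] * 3 + [False] * 4)
        s = pn.separation_score(scores, member)
        assert s == pytest.approx(4.27, abs=0.01)
        ann = pn.annotate_clusters(
            {"isg": scores}, np.where(member, "c1", "c0")
        )
        assigned = ann[(ann.cluster == "c1") & (ann.type == "isg")].iloc[0]
        assert assigned["assigned"]

    def test_indistinct_cluster_unannotated(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(0, 1, 100)
        labels = np.repeat(["a", "b"], 50)
        ann = pn.annotate_clusters({"isg": scores}, labels)
        assert pn.cluster_assignments(ann) == {"a": "unannotated", "b": "unannotated"}

    def test_affine_invariance_of_score(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(0, 1, 50)
        member = rng.random(50) < 0.4
        s0 = pn.separation_score(scores, member)
        assert pn.separation_score(scores + 17.3, member) == pytest.approx(s0, abs=1e-12)
        assert pn.separation_score(scores * 4.2, member) == pytest.approx(s0, abs=1e-12)

    def test_cluster_covering_everything_is_error(self):
        with pytest.raises(ValueError, match="other"):
            pn.separation_score(np.ones(5), np.ones(5, bool))

    def test_multiple_qualifying_types_assigned_by_argmax(self):
        rng = np.random.default_rng(9)
        labels = np.array(["c1"] * 10 + ["c0"] * 20)
        in_c1 = labels == "c1"
        # both types separate c1, A more sharply than B
        scores_a = np.where(in_c1, 2.0, 0.0) + rng.normal(0, 0.05, 30)
        scores_b = np.where(in_c1, 2.0, 0.0) + rng.normal(0, 0.5, 30)
        ann = pn.annotate_clusters({"A": scores_a, "B": scores_b}, labels)
        c1 = ann[ann.cluster == "c1"]
        assert c1["qualifies"].sum() == 2
        assert c1.loc[c1["assigned"], "type"].iloc[0] == "A"


class TestCellTypeHistogram:
    def test_adjacent_type_mass_concentrates_near_plaques(self, small_field, two_type_spec):
        panel, types = two_type_spec
        cm, labels = pn.make_cells(types, 200, panel, small_field, seed=7)
        norm = pn.pearson_residuals(cm.counts, cm.genes)
        cl = pn.reduce_and_cluster(norm, seed=7)
        scores = {
            t.type_name: pn.score_gene_set(norm.residuals, cm.genes, list(t.marker_genes), seed=7)
            for t in types
        }
        ann = pn.annotate_clusters(scores, cl)
        profiles = pn.celltype_distance_histogram(
            ann, cl, cm.centroids(), small_field, 5.0, 200.0
        )
        near = profiles["tcell"]
        share = near.raw_count[: int(69 // 5) + 1].sum() / near.raw_count.sum()
        assert share >= 0.7
        uni = profiles["microglia"]
        uni_share = uni.raw_count[: int(69 // 5) + 1].sum() / uni.raw_count.sum()
        assert uni_share < share

    def test_zero_plaques_gives_empty_profiles(self, unit_scale, two_type_spec):
        panel, types = two_type_spec
        field = pn.field_from_mask(np.zeros((64, 64), bool), unit_scale)
        uniform = [t for t in types if t.spatial_rule == "uniform"]
        cm, _ = pn.make_cells(uniform, 30, panel, field, seed=8)
        labels = np.zeros(30, dtype=int)
        labels[:15] = 1
        scores = {"microglia": pn.score_gene_set(cm.counts, cm.genes, list(uniform[0].marker_genes))}
        ann = pn.annotate_clusters(scores, labels)
        profiles = pn.celltype_distance_histogram(ann, labels, cm.centroids(), field)
        for prof in profiles.values():
            assert prof.n_reference_points == 0
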