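"""Transition-mode classification: normalisation, selection, clustering,
template matching and the snapshot/transient DEG rules."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tdcss import (
    ConfigError,
    CountSimConfig,
    HUMAN5_TEMPLATES,
    MOUSE6_TEMPLATES,
    SchemaError,
    StateProfileMatrix,
    alternative_tig_rule,
    anova_select_genes,
    build_state_profiles,
    classify_transition_modes,
    cpm_normalize,
    kmeans_transition_clusters,
    merge_clusters_to_classes,
    simulate_state_counts,
    snapshot_deg,
    tig_overlap,
)
from tdcss.classify import expression_matrix, size_factors

from conftest import tiny_matrix


class TestCpm:
    def test_columns_sum_to_one_million(self, planted_matrix):
        matrix, _ = planted_matrix
        cpm = cpm_normalize(matrix)
        np.testing.assert_allclose(cpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_cell_with_total_one_million_unchanged(self):
        counts = np.array([[600_000, 1], [400_000, 1]])
        m = tiny_matrix(counts, ["pre", "pre"])
        cpm = cpm_normalize(m)
        np.testing.assert_allclose(cpm[:, 0], counts[:, 0])

    def test_single_count_in_two_million_total_is_half_cpm(self):
        counts = np.array([[2], [2_000_000 - 2]])
        m = tiny_matrix(counts, ["pre"])
        assert cpm_normalize(m)[0, 0] == pytest.approx(1.0)

    def test_zero_total_cell_raises_naming_the_cell(self):
        counts = np.array([[1, 0], [1, 0]])
        m = tiny_matrix(counts, ["pre", "pre"])
        with pytest.raises(SchemaError, match="c1"):
            cpm_normalize(m)


class TestSizeFactors:
    def test_pure_library_scaling_is_recovered(self):
        rng = np.random.default_rng(0)
        base = rng.integers(20, 100, size=50)
        lib = np.array([0.5, 1.0, 2.0, 1.5])
        counts = np.maximum(1, (base[:, None] * lib[None, :]).astype(int))
        m = tiny_matrix(counts, ["pre", "pre", "transition", "transition"])
        sf = size_factors(m)
        np.testing.assert_allclose(sf / sf[1], lib / lib[1], rtol=0.05)


class TestAnova:
    def test_f_statistic_matches_hand_computation(self):
        # 2 genes x 9 cells in three states; expression passed explicitly
        expr = np.array(
            [
                [1.0, 2.0, 3.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0],
                [5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0],
            ]
        )
        states = ["pre"] * 3 + ["transition"] * 3 + ["activated"] * 3
        m = tiny_matrix(np.ones_like(expr, dtype=int), states)
        res = anova_select_genes(m, alpha=0.05, expression=expr)

        groups = [expr[0, :3], expr[0, 3:6], expr[0, 6:]]
        grand = expr[0].mean()
        ms_between = sum(3 * (g.mean() - grand) ** 2 for g in groups) / (3 - 1)
        ms_within = sum(((g - g.mean()) ** 2).sum() for g in groups) / (9 - 3)
        assert res.loc[0, "F"] == pytest.approx(ms_between / ms_within)

    def test_equal_constant_groups_give_f_zero_and_no_selection(self):
        expr = np.full((1, 6), 7.0)
        m = tiny_matrix(np.ones_like(expr, dtype=int), ["pre"] * 3 + ["activated"] * 3)
        res = anova_select_genes(m, alpha=0.05, expression=expr)
        assert res.loc[0, "F"] == 0.0
        assert not res.loc[0, "selected"]

    def test_zero_within_variance_with_different_means_is_degenerate(self):
        expr = np.array([[1.0, 1.0, 1.0, 2.0, 2.0, 2.0]])
        m = tiny_matrix(np.ones_like(expr, dtype=int), ["pre"] * 3 + ["activated"] * 3)
        res = anova_select_genes(m, alpha=0.05, expression=expr)
        assert res.loc[0, "p"] == 0.0
        assert res.loc[0, "degenerate"]

    def test_state_with_single_observation_raises(self):
        counts = np.ones((2, 3), dtype=int)
        m = tiny_matrix(counts, ["pre", "pre", "activated"])
        with pytest.raises(SchemaError):
            anova_select_genes(m)


class TestStateProfiles:
    def test_constant_gene_zscores_to_zero_row(self):
        counts = np.full((2, 8), 50, dtype=int)
        m = tiny_matrix(counts, ["pre", "pre", "transition", "transition",
                                 "activated", "activated", "silent", "silent"])
        prof = build_state_profiles(m, ["g0"], zscore=True)
        np.testing.assert_array_equal(prof.values.loc["g0"].to_numpy(), 0.0)

    def test_zscored_rows_have_mean_zero_sd_one(self, planted_matrix):
        matrix, truth = planted_matrix
        degs = truth.loc[truth["class"] == "TIG", "gene_id"].tolist()
        prof = build_state_profiles(matrix, degs, zscore=True)
        vals = prof.values.to_numpy()
        np.testing.assert_allclose(vals.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(vals.std(axis=1), 1.0, atol=1e-9)

    def test_per_donor_averaging_matches_groupby_oracle(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(10, 100, size=(4, 12))
        states = ["pre"] * 6 + ["transition"] * 6
        donors = (["d1"] * 3 + ["d2"] * 3) * 2
        m = tiny_matrix(counts, states, donor=np.array(donors))
        prof = build_state_profiles(m, ["g0", "g1"], per_donor=True, zscore=False)

        expr = expression_matrix(m)
        df = pd.DataFrame(expr.T)
        df["state"], df["donor"] = states, donors
        oracle = df.groupby(["state", "donor"]).mean().groupby("state").mean().T
        for st in ("pre", "transition"):
            np.testing.assert_allclose(
                prof.values[st].to_numpy(), oracle[st].to_numpy()[:2], rtol=1e-12
            )

    def test_planted_tig_profile_peaks_at_transition(self, planted_matrix):
        matrix, truth = planted_matrix
        degs = truth.loc[truth["class"] == "TIG", "gene_id"].tolist()
        prof = build_state_profiles(matrix, degs, zscore=False)
        vals = prof.values
        assert (vals.idxmax(axis=1) == "transition").mean() > 0.95

    def test_unknown_state_raises(self, planted_matrix):
        matrix, truth = planted_matrix
        with pytest.raises(SchemaError):
            build_state_profiles(matrix, ["eig_0000"], states=["pre", "resting"])

    def test_labels_invariant_under_affine_expression_transform(self):
        rng = np.random.default_rng(9)
        expr = rng.normal(5, 1, size=(30, 40))
        expr[:10, 10:20] += 3.0  # induced at transition
        states = ["pre"] * 10 + ["transition"] * 10 + ["activated"] * 10 + ["silent"] * 10
        m = tiny_matrix(np.ones_like(expr, dtype=int), states)
        genes = [f"g{i}" for i in range(30)]
        p1 = build_state_profiles(m, genes, expression=expr)
        p2 = build_state_profiles(m, genes, expression=2.5 * expr + 7.0)
        np.testing.assert_allclose(
            p1.values.to_numpy(), p2.values.to_numpy(), atol=1e-9
        )


class TestKMeansAndMerge:
    def test_two_separated_patterns_are_perfectly_split(self):
        rng = np.random.default_rng(1)
        a = np.tile([1.0, -1.0, -1.0, 1.0], (30, 1)) + rng.normal(0, 0.05, (30, 4))
        b = np.tile([-1.0, 1.0, -1.0, -1.0], (30, 1)) + rng.normal(0, 0.05, (30, 4))
        prof = StateProfileMatrix(
            values=pd.DataFrame(np.vstack([a, b]),
                                columns=["pre", "transition", "activated", "silent"])
        )
        labels, _ = kmeans_transition_clusters(prof, k=2, seed=0)
        truth = [0] * 30 + [1] * 30
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_identical_rows_do_not_crash(self):
        prof = StateProfileMatrix(
            values=pd.DataFrame(np.ones((10, 4)),
                                columns=["pre", "transition", "activated", "silent"])
        )
        labels, centroids = kmeans_transition_clusters(prof, k=2, seed=0)
        np.testing.assert_allclose(centroids[0], centroids[1])

    def test_seeded_clustering_is_deterministic(self, planted_matrix):
        matrix, truth = planted_matrix
        degs = truth.loc[truth["class"] != "spikein", "gene_id"].tolist()[:100]
        prof = build_state_profiles(matrix, degs)
        l1, _ = kmeans_transition_clusters(prof, k=5, seed=11)
        l2, _ = kmeans_transition_clusters(prof, k=5, seed=11)
        np.testing.assert_array_equal(l1, l2)

    def test_k_larger_than_gene_count_raises(self):
        prof = StateProfileMatrix(values=pd.DataFrame(np.ones((3, 4))))
        with pytest.raises(ConfigError):
            kmeans_transition_clusters(prof, k=5, seed=0)

    def test_exact_tig_template_maps_to_tig_with_correlation_one(self):
        centroids = MOUSE6_TEMPLATES["TIG"][None, :]
        out = merge_clusters_to_classes(centroids, MOUSE6_TEMPLATES)
        assert out[0][0] == "TIG"
        assert out[0][1] == pytest.approx(1.0)

    def test_negated_transient_template_maps_to_trg_in_human_set(self):
        centroids = -HUMAN5_TEMPLATES["TIG"][None, :]  # down-then-up
        out = merge_clusters_to_classes(centroids, HUMAN5_TEMPLATES)
        assert out[0][0] == "TRG"

    def test_low_correlation_centroid_is_unclassified(self):
        centroids = np.array([[0.1, -0.05, 0.02, -0.07]])
        out = merge_clusters_to_classes(centroids, MOUSE6_TEMPLATES, min_correlation=0.6)
        assert out[0][0] == "unclassified"

    def test_template_length_mismatch_raises(self):
        with pytest.raises(ConfigError):
            merge_clusters_to_classes(np.ones((1, 3)), MOUSE6_TEMPLATES)


class TestEndToEndClassification:
    def test_planted_classes_recovered(self, planted_matrix):
        matrix, truth = planted_matrix
        asg = classify_transition_modes(matrix, mode="mouse6", seed=17)
        tmap = dict(zip(truth["gene_id"], truth["class"]))
        for cls in ["EIG", "ERG", "LIG", "LRG", "SIG", "TIG"]:
            pred = asg.genes_in_class(cls)
            true = {g for g, c in tmap.items() if c == cls}
            tp = len(pred & true)
            assert tp / max(len(pred), 1) >= 0.9, cls
            assert tp / len(true) >= 0.9, cls

    def test_human_style_three_state_mode_with_donor_averaging(self):
        cfg = CountSimConfig(
            states=("pre", "transition", "activated"), n_donors=3,
            n_genes_per_class=30, n_null_genes=200, n_cells_per_state=18,
            seed=2,
        )
        m, truth = simulate_state_counts(cfg)
        asg = classify_transition_modes(m, mode="human5", seed=2)
        tmap = dict(zip(truth["gene_id"], truth["class"]))
        for cls in ["EIG", "LIG", "LEG", "TRG", "TIG"]:
            pred = asg.genes_in_class(cls)
            true = {g for g, c in tmap.items() if c == cls}
            tp = len(pred & true)
            assert tp / max(len(pred), 1) >= 0.85, cls
            assert tp / len(true) >= 0.85, cls

    def test_tiny_alpha_on_null_data_gives_empty_assignment(self):
        cfg = CountSimConfig(n_genes_per_class=0, n_null_genes=100,
                             n_cells_per_state=10, seed=3)
        m, _ = simulate_state_counts(cfg)
        asg = classify_transition_modes(m, mode="mouse6", alpha=1e-12, seed=0)
        assert len(asg.table) == 0
        assert asg.class_counts == {}

    def test_mouse_mode_requires_silent_state(self):
        cfg = CountSimConfig(states=("pre", "transition", "activated"),
                             n_genes_per_class=5, n_null_genes=20,
                             n_cells_per_state=5, seed=0)
        m, _ = simulate_state_counts(cfg)
        with pytest.raises(SchemaError):
            classify_transition_modes(m, mode="mouse6")


class TestSnapshotDeg:
    def test_identical_groups_give_empty_deg_set(self):
        rng = np.random.default_rng(2)
        counts = np.tile(rng.integers(5, 50, size=(8, 1)), (1, 12))
        m = tiny_matrix(counts, ["activated"] * 6 + ["pre"] * 6)
        res = snapshot_deg(m, "activated", "pre")
        assert res["selected"].sum() == 0

    def _fixture(self):
        # 8 genes x 12 cells (6 activated, 6 pre); two genes strongly up,
        # one gene expressed in exactly `min_cells` cells, the rest flat.
        counts = np.array(
            [
                [800, 820, 790, 810, 805, 795, 100, 99, 101, 100, 98, 102],
                [400, 410, 390, 405, 395, 400, 50, 49, 51, 50, 52, 48],
                [100, 101, 99, 100, 100, 100, 100, 101, 99, 100, 100, 100],
                [30, 0, 0, 0, 0, 0, 0, 0, 0, 0, 2, 3],  # 4 cells only
                [60, 62, 58, 61, 59, 60, 55, 56, 54, 57, 55, 53],
                [5, 6, 4, 5, 5, 5, 5, 4, 6, 5, 5, 5],
                [200, 205, 195, 201, 199, 200, 198, 202, 200, 197, 203, 200],
                [1000, 990, 1010, 1005, 995, 1000, 1002, 998, 1000, 1001, 999, 1000],
            ]
        )
        states = ["activated"] * 6 + ["pre"] * 6
        return tiny_matrix(counts, states)

    def test_filter_chain_matches_hand_applied_oracle(self):
        from scipy.stats import mannwhitneyu
        from statsmodels.stats.multitest import multipletests

        m = self._fixture()
        res = snapshot_deg(m, "activated", "pre", min_cells=4, min_fold=4)
        got = set(res.loc[res["selected"], "gene_id"])

        # literal sequential filters applied by hand
        cpm = m.counts / m.counts.sum(axis=0, keepdims=True) * 1e6
        ia, ib = slice(0, 6), slice(6, 12)
        survivors, pvals = [], []
        for g in range(m.counts.shape[0]):
            if (m.counts[g] > 0).sum() <= 4:
                continue
            fold = (cpm[g, ia].mean() + 1) / (cpm[g, ib].mean() + 1)
            if fold < 4:
                continue
            p = mannwhitneyu(cpm[g, ia], cpm[g, ib], alternative="two-sided").pvalue
            survivors.append(m.gene_ids[g])
            pvals.append(p)
        p_adj = multipletests(pvals, method="fdr_bh")[1]
        want = {g for g, q in zip(survivors, p_adj) if q < 0.05}
        assert got == want
        assert got == {"g0", "g1"}

    def test_gene_in_exactly_min_cells_is_excluded(self):
        m = self._fixture()
        res = snapshot_deg(m, "activated", "pre", min_cells=4, min_fold=1.0)
        assert "g3" not in set(res["gene_id"])

    def test_empty_group_raises(self):
        m = self._fixture()
        with pytest.raises(SchemaError):
            snapshot_deg(m, "activated", "silent")


class TestTigOverlap:
    def test_disjoint_sets_have_zero_intersections(self):
        out = tig_overlap({"a", "b"}, {"s1": {"c"}, "s2": {"d"}})
        assert out["pairwise"] == {"s1": 0, "s2": 0}
        assert out["in_any"] == 0
        assert out["tig_only"] == ["a", "b"]

    def test_subset_intersection_equals_tig_size(self):
        out = tig_overlap({"a", "b"}, {"s": {"a", "b", "c"}})
        assert out["pairwise"]["s"] == 2
        assert out["tig_only"] == []

    def test_random_sets_match_direct_set_arithmetic(self):
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(50)]
        tigs = set(rng.choice(universe, 15, replace=False))
        sets = {
            name: set(rng.choice(universe, 20, replace=False))
            for name in ("A", "B", "C")
        }
        out = tig_overlap(tigs, sets)
        for name in sets:
            assert out["pairwise"][name] == len(tigs & sets[name])
        assert out["in_any"] == len(tigs & (sets["A"] | sets["B"] | sets["C"]))


class TestAlternativeTigRule:
    def test_planted_tigs_recovered(self, planted_matrix):
        matrix, truth = planted_matrix
        tigs_true = set(truth.loc[truth["class"] == "TIG", "gene_id"])
        got, _ = alternative_tig_rule(matrix)
        assert len(got & tigs_true) / len(tigs_true) >= 0.9

    def test_sustained_induction_is_excluded(self, planted_matrix):
        matrix, truth = planted_matrix
        eigs = set(truth.loc[truth["class"] == "EIG", "gene_id"])
        got, _ = alternative_tig_rule(matrix)
        assert len(got & eigs) == 0

    def test_flat_genes_are_excluded(self, planted_matrix):
        matrix, truth = planted_matrix
        nulls = set(truth.loc[truth["class"] == "null", "gene_id"])
        got, _ = alternative_tig_rule(matrix)
        assert len(got & nulls) <= 0.01 * len(nulls)

    def test_missing_state_raises(self):
        m = tiny_matrix(np.ones((2, 4), dtype=int), ["pre", "pre", "activated", "activated"])
        with pytest.raises(SchemaError):
            alternative_tig_rule(m)
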