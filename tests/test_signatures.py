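import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from oracles import linkage_to_merges, naive_average_linkage, same_merge_sequence
from pdxsynergy.signatures import (
    GeneSignature,
    cluster_profiles,
    fold_changes,
    normalize_antibody_array,
    percent_positive,
    profile_similarity,
    qc_filter_cells,
    score_signatures,
    signature_pca,
)
from pdxsynergy.synthgen import SimulationSpec, sim_cell_qc_metrics, sim_expression_cohort


def random_expr(seed, n_genes=50, n_samples=6):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(2.0, 1.0, size=(n_genes, n_samples)),
        index=[f"G{i:03d}" for i in range(n_genes)],
        columns=[f"S{j}" for j in range(n_samples)],
    )


class TestScoreSignatures:
    def test_constant_matrix_scores_the_constant(self):
        expr = pd.DataFrame(3.5, index=["A", "B", "C"], columns=["s1", "s2"])
        scores = score_signatures(expr, [GeneSignature("sig", ("A", "B"))])
        assert (scores.values == 3.5).all()

    def test_single_gene_signature_equals_gene_row(self):
        expr = random_expr(0)
        scores = score_signatures(expr, [GeneSignature("one", ("G007",))])
        np.testing.assert_allclose(scores.loc["one"], expr.loc["G007"])

    def test_matches_brute_force_means(self):
        expr = random_expr(1)
        rng = np.random.default_rng(2)
        sigs = [
            GeneSignature(f"sig{k}", tuple(rng.choice(expr.index, 8, replace=False)))
            for k in range(3)
        ]
        scores = score_signatures(expr, sigs)
        for sig in sigs:
            for sample in expr.columns:
                brute = np.mean([expr.loc[g, sample] for g in sig.genes])
                assert scores.loc[sig.name, sample] == pytest.approx(brute)

    def test_invariant_to_gene_order_and_absent_genes(self):
        expr = random_expr(3)
        genes = ("G001", "G010", "G020")
        a = score_signatures(expr, [GeneSignature("s", genes)])
        with pytest.warns(UserWarning, match="absent"):
            b = score_signatures(
                expr, [GeneSignature("s", tuple(reversed(genes)) + ("MISSING",))]
            )
        np.testing.assert_allclose(a.values, b.values)

    def test_all_signatures_absent_errors(self):
        expr = random_expr(4)
        with pytest.raises(ValueError, match="no signature"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                score_signatures(expr, [GeneSignature("s", ("NOPE", "NADA"))])

    def test_planted_cohort_scores_recovered_noise_free(self):
        expr, truth = sim_expression_cohort(
            SimulationSpec(seed=0, noise_cv=0.0),
            effects={"SIG1": np.linspace(0, 2, 8), "SIG2": 1.0},
        )
        sigs = [GeneSignature(n, tuple(f"G{20 * j + i + 1:04d}" for i in range(20)))
                for j, n in enumerate(["SIG1", "SIG2", "SIG3"])]
        scores = score_signatures(expr, sigs)
        np.testing.assert_allclose(scores.values, truth.values, atol=1e-12)


class TestClusterProfiles:
    def test_duplicated_profile_merges_at_height_zero(self):
        profiles = random_expr(5, n_genes=4, n_samples=6)
        profiles.iloc[1] = profiles.iloc[0]
        result = cluster_profiles(profiles)
        assert result.row_linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_pair_sits_at_distance_two(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        profiles = pd.DataFrame([base, -base, base * 2 + 5], index=list("abc"))
        dist = squareform(pdist(profiles.to_numpy(), metric="correlation"))
        assert dist[0, 1] == pytest.approx(2.0)
        assert dist[0, 2] == pytest.approx(0.0, abs=1e-12)
        cluster_profiles(profiles)  # well-defined despite the perfect pair

    def test_merge_sequence_matches_naive_agglomeration(self):
        for seed in range(10):
            profiles = random_expr(seed, n_genes=7, n_samples=6)
            result = cluster_profiles(profiles)
            dist = squareform(pdist(profiles.to_numpy(), metric="correlation"))
            assert same_merge_sequence(
                linkage_to_merges(result.row_linkage), naive_average_linkage(dist)
            )

    def test_zero_variance_profile_named_in_error(self):
        profiles = random_expr(6, n_genes=4, n_samples=5)
        profiles.iloc[2] = 7.0
        with pytest.raises(ValueError, match=str(profiles.index[2])):
            cluster_profiles(profiles)


class TestProfileSimilarity:
    def test_identical_rows_correlate_perfectly(self):
        profiles = random_expr(7, n_genes=3, n_samples=5)
        profiles.iloc[1] = profiles.iloc[0] * 2 + 1  # affine copy
        sim, summary = profile_similarity(profiles)
        assert sim.iloc[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(sim), 1.0)
        assert summary["max"] == pytest.approx(1.0)

    def test_matches_direct_pearson_and_counts_pairs(self):
        profiles = random_expr(8, n_genes=14, n_samples=5)
        sim, summary = profile_similarity(profiles)
        assert summary["n_pairs"] == 91  # C(14, 2)
        i, j = 3, 11
        expected = np.corrcoef(profiles.iloc[i], profiles.iloc[j])[0, 1]
        assert sim.iloc[i, j] == pytest.approx(expected)
        assert sim.equals(sim.T)

    def test_planted_covariation_signs(self):
        effects = {"SIG1": np.linspace(0, 2, 8), "SIG2": np.linspace(0, 2, 8),
                   "SIG3": np.linspace(2, 0, 8)}
        expr, _ = sim_expression_cohort(SimulationSpec(seed=1, noise_cv=0.0), effects=effects)
        sigs = [GeneSignature(n, tuple(f"G{20 * j + i + 1:04d}" for i in range(20)))
                for j, n in enumerate(["SIG1", "SIG2", "SIG3"])]
        sim, summary = profile_similarity(score_signatures(expr, sigs))
        assert sim.loc["SIG1", "SIG2"] == pytest.approx(1.0)
        assert sim.loc["SIG1", "SIG3"] == pytest.approx(-1.0)
        assert summary["n_negative_pairs"] == 2


class TestQcFilterCells:
    def test_identical_cells_all_kept(self):
        metrics = pd.DataFrame(
            {"n_feature": [100] * 5, "n_count": [300] * 5, "percent_mt": [5.0] * 5}
        )
        keep, _ = qc_filter_cells(metrics)
        assert keep.all()  # MAD = 0 but comparisons are strict

    def test_hard_mito_cap_applies_in_low_mito_sample(self):
        rng = np.random.default_rng(0)
        metrics = pd.DataFrame(
            {
                "n_feature": rng.uniform(900, 1100, 60),
                "n_count": rng.uniform(2900, 3100, 60),
                # median ~21, MAD ~1.5: the MAD cutoff (~25.5) exceeds the cap
                "percent_mt": np.r_[rng.uniform(18.0, 24.0, 59), 30.0],
            }
        )
        keep, cutoffs = qc_filter_cells(metrics)
        # MAD-based cutoff would sit far above 25; the hard cap rules
        assert cutoffs.loc["all", "percent_mt_cutoff"] == pytest.approx(25.0)
        assert not keep.iloc[-1]
        assert keep.iloc[:-1].all()

    def test_mito_median_ignores_dying_cells(self):
        rng = np.random.default_rng(1)
        mt = np.r_[rng.uniform(2, 6, 50), np.full(10, 80.0)]  # dying cells > 50%
        metrics = pd.DataFrame(
            {"n_feature": rng.uniform(900, 1100, 60),
             "n_count": rng.uniform(2900, 3100, 60), "percent_mt": mt}
        )
        _, cutoffs = qc_filter_cells(metrics)
        assert cutoffs.loc["all", "percent_mt_cutoff"] < 20  # not dragged up to 25

    def test_planted_outliers_removed_exactly(self):
        metrics, planted = sim_cell_qc_metrics(SimulationSpec(seed=0))
        keep, _ = qc_filter_cells(metrics)
        assert set(metrics.index[~keep]) == planted

    def test_median_cell_appendix_leaves_mask_unchanged(self):
        metrics, _ = sim_cell_qc_metrics(SimulationSpec(seed=1))
        keep_before, _ = qc_filter_cells(metrics)
        median_cell = metrics.median(numeric_only=True)
        extra = pd.DataFrame([{"sample": "S1", **median_cell}], index=["median-cell"])
        keep_after, _ = qc_filter_cells(pd.concat([metrics, extra]))
        assert keep_after.loc["median-cell"]
        assert (keep_after.loc[metrics.index] == keep_before).all()

    def test_per_sample_cutoffs_are_independent(self):
        # deep and shallow samples: each is uniform within itself, so a
        # pooled cutoff would reject one of them wholesale
        a = pd.DataFrame(
            {"sample": "A", "n_feature": [1000.0] * 30, "n_count": [3000.0] * 30,
             "percent_mt": [3.0] * 30}
        )
        b = pd.DataFrame(
            {"sample": "B", "n_feature": [5000.0] * 30, "n_count": [15000.0] * 30,
             "percent_mt": [3.0] * 30}
        )
        keep, cutoffs = qc_filter_cells(pd.concat([a, b], ignore_index=True))
        assert keep.all()  # each sample judged against its own center
        assert cutoffs.loc["A", "n_count_high"] < cutoffs.loc["B", "n_count_low"]


class TestPercentPositive:
    def test_all_zero_and_all_positive_genes(self):
        expr = pd.DataFrame(
            [[0.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0]],
            index=["ZERO", "POS"], columns=[f"c{i}" for i in range(5)],
        )
        assert percent_positive(expr, "ZERO").item() == 0.0
        assert percent_positive(expr, "POS").item() == 100.0

    def test_matches_hand_count_and_averages_gene_panel(self):
        expr = pd.DataFrame(
            {"c1": [1.0, 0.0, 0.0], "c2": [0.0, 0.0, 0.0], "c3": [2.0, 1.0, 0.0],
             "c4": [0.0, 3.0, 0.0], "c5": [0.5, 0.5, 0.0]},
            index=["AKT1", "AKT2", "AKT3"],
        )
        # per-cell mean over AKT1-3: 1/3, 0, 1, 1, 1/3 -> 4 of 5 positive
        result = percent_positive(expr, ["AKT1", "AKT2", "AKT3"])
        assert result.item() == pytest.approx(80.0)

    def test_grouped_by_model(self):
        expr = pd.DataFrame(
            {"c1": [1.0], "c2": [0.0], "c3": [1.0], "c4": [1.0]}, index=["PIK3CA"]
        )
        groups = pd.Series({"c1": "m1", "c2": "m1", "c3": "m2", "c4": "m2"})
        result = percent_positive(expr, "PIK3CA", groups=groups)
        assert result["m1"] == pytest.approx(50.0)
        assert result["m2"] == pytest.approx(100.0)


class TestSignaturePca:
    def test_full_gene_signature_equals_unrestricted_pca(self):
        from sklearn.decomposition import PCA
        from sklearn.preprocessing import StandardScaler

        expr = random_expr(10, n_genes=12, n_samples=30)
        sig = GeneSignature("all", tuple(expr.index))
        result = signature_pca(expr, sig, k=3)
        X = StandardScaler().fit_transform(expr.to_numpy().T)
        expected = PCA(n_components=3, svd_solver="full").fit_transform(X)
        np.testing.assert_allclose(np.abs(result.scores.values), np.abs(expected), atol=1e-8)

    def test_rank_one_data_recovers_planted_direction(self):
        rng = np.random.default_rng(11)
        direction = rng.normal(size=5)
        weights = rng.normal(size=40)
        expr = pd.DataFrame(
            np.outer(direction, weights),
            index=[f"G{i}" for i in range(5)], columns=[f"c{j}" for j in range(40)],
        )
        result = signature_pca(expr, GeneSignature("s", tuple(expr.index)), k=1, scale=False)
        corr = np.corrcoef(result.scores["PC1"], weights)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-8)

    def test_scores_centered_and_components_orthogonal(self):
        expr = random_expr(12, n_genes=20, n_samples=25)
        result = signature_pca(expr, GeneSignature("s", tuple(expr.index[:15])), k=4)
        np.testing.assert_allclose(result.scores.mean(axis=0), 0.0, atol=1e-10)
        gram = result.loadings.T @ result.loadings
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)

    def test_two_gene_intersection_runs_with_warning(self):
        expr = random_expr(13, n_genes=10, n_samples=12)
        sig = GeneSignature("sparse", ("G000", "G001", "ABSENT1", "ABSENT2"))
        with pytest.warns(UserWarning, match="intersection"):
            result = signature_pca(expr, sig, k=1)
        assert result.genes_used == ("G000", "G001")

    def test_k_beyond_rank_rejected(self):
        expr = random_expr(14, n_genes=5, n_samples=8)
        with pytest.raises(ValueError, match="rank"):
            signature_pca(expr, GeneSignature("s", tuple(expr.index)), k=5)


class TestAntibodyArray:
    def test_probe_identical_to_single_control_normalizes_to_one(self):
        out = normalize_antibody_array([400.0], [40.0], [400.0], [40.0])
        assert out[0] == pytest.approx(1.0)

    def test_global_exposure_change_cancels(self):
        raw, bg = np.array([300.0, 150.0]), np.array([30.0, 20.0])
        pos, pos_bg = np.array([500.0]), np.array([25.0])
        base = normalize_antibody_array(raw, bg, pos, pos_bg)
        doubled = normalize_antibody_array(2 * raw, bg, 2 * pos, pos_bg)
        np.testing.assert_allclose(base, doubled)

    def test_four_probe_membrane_matches_hand_computation(self):
        raw = np.array([100.0, 200.0, 50.0, 400.0])
        bg = np.array([10.0, 20.0, 10.0, 40.0])
        pos, pos_bg = np.array([300.0, 330.0]), np.array([30.0, 30.0])
        control_level = (300 / 30 + 330 / 30) / 2  # 10.5
        expected = (raw / bg) / control_level
        np.testing.assert_allclose(normalize_antibody_array(raw, bg, pos, pos_bg), expected)

    def test_fold_change_is_probewise_ratio(self):
        treated = np.array([2.0, 0.5, 1.0])
        control = np.array([1.0, 1.0, 2.0])
        np.testing.assert_allclose(fold_changes(treated, control), [2.0, 0.5, 0.5])

    def test_nonpositive_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            normalize_antibody_array([100.0], [0.0], [300.0], [30.0])
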