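import numpy as np
import pandas as pd
import pytest

from netcollapse.edges import edge_vector
from netcollapse.structure import (PLSStructureFunction, WScoreModel,
                                   apply_wscores, atrophy_pca_scores,
                                   fit_plsr_components, fit_wscore_model,
                                   mds_embed, network_summary_map,
                                   reconstruct_fc_from_components,
                                   ridge_function_scores,
                                   split_half_reliability,
                                   typical_patients_lda)


class TestWScores:
    def make_reference(self, rng, n=200, R=10):
        age = rng.uniform(50, 85, n)
        sex = rng.integers(0, 2, n).astype(float)
        cov = pd.DataFrame({"age": age, "sex": sex})
        slopes = rng.normal(-0.01, 0.003, R)
        intercept = rng.uniform(0.4, 0.8, R)
        gm = intercept + np.outer(age, slopes) + 0.05 * rng.normal(size=(n, R))
        return gm, cov, slopes

    def test_known_coefficients_within_2se(self, rng):
        gm, cov, slopes = self.make_reference(rng)
        model = fit_wscore_model(gm, cov)
        n = len(cov)
        se = 0.05 / (np.std(cov["age"]) * np.sqrt(n))
        assert np.all(np.abs(model.coef_[1] - slopes) < 2.5 * se)

    def test_exact_linear_reference_rejected(self, rng):
        age = rng.uniform(50, 85, 50)
        gm = np.outer(age, np.ones(3)) * 0.01 + 0.5
        with pytest.raises(ValueError, match="zero residual sd"):
            fit_wscore_model(gm, pd.DataFrame({"age": age}))

    def test_intercept_free_prediction_is_mean(self, rng):
        gm = rng.normal(size=(60, 4)) + 5.0
        cov = pd.DataFrame({"dummy": rng.normal(size=60) * 1e-12 + 1e-6})
        # near-constant covariate: prediction ~ reference mean
        model = fit_wscore_model(gm, cov)
        pred = model.predict(cov.iloc[:1])
        assert np.allclose(pred[0], gm.mean(axis=0), atol=0.05)

    def test_match_gives_zero_wscore(self, rng):
        gm, cov, _ = self.make_reference(rng)
        model = fit_wscore_model(gm, cov)
        pred = model.predict(cov.iloc[3])
        w = apply_wscores(pred[0], cov.iloc[3], model)
        assert np.allclose(w, 0.0, atol=1e-10)

    def test_atrophy_positive_convention_at_threshold(self, rng):
        """1.5 residual-sd below expected gray matter scores +1.5, the
        conventional significance threshold for atrophy."""
        gm, cov, _ = self.make_reference(rng)
        model = fit_wscore_model(gm, cov)
        pred = model.predict(cov.iloc[0])[0]
        w = apply_wscores(pred - 1.5 * model.residual_sd_, cov.iloc[0], model)
        assert np.allclose(w, 1.5, atol=1e-10)

    def test_brute_force_recomputation(self, rng):
        gm, cov, _ = self.make_reference(rng)
        model = fit_wscore_model(gm, cov)
        x = rng.normal(size=10) + 0.5
        row = cov.iloc[7]
        w = apply_wscores(x, row, model)
        manual = (
            (model.coef_[0] + model.coef_[1] * row["age"]
             + model.coef_[2] * row["sex"]) - x
        ) / model.residual_sd_
        assert np.allclose(w, manual, atol=1e-12)

    def test_rank_deficient_covariates_named(self, rng):
        gm = rng.normal(size=(50, 3))
        cov = pd.DataFrame({"a": rng.normal(size=50)})
        cov["b"] = 2 * cov["a"]
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_wscore_model(gm, cov)

    def test_missing_covariate_rejected(self, rng):
        gm, cov, _ = self.make_reference(rng)
        model = fit_wscore_model(gm, cov)
        bad = cov.iloc[0].copy()
        bad["age"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            apply_wscores(gm[0], bad, model)


class TestPLSR:
    def test_rank_one_planted_recovery(self, rng):
        s = rng.normal(size=80)
        u = rng.normal(size=30)
        v = rng.normal(size=200)
        atrophy = np.outer(s, u) + 1e-4 * rng.normal(size=(80, 30))
        fc = np.outer(s, v) + 1e-4 * rng.normal(size=(80, 200))
        model = fit_plsr_components(atrophy, fc, n_components=2)
        r = np.corrcoef(model.structure_scores_[:, 0], s)[0, 1]
        assert abs(r) > 0.99

    def test_global_severity_tracks_mean_atrophy(self, sf_cohort):
        model = fit_plsr_components(sf_cohort.atrophy, sf_cohort.fc_edges, 3)
        r = np.corrcoef(model.structure_scores_[:, 0],
                        sf_cohort.atrophy.mean(axis=1))[0, 1]
        assert abs(r) > 0.99

    def test_permuted_fc_kills_score_coupling(self, sf_cohort, rng):
        perm = rng.permutation(len(sf_cohort.fc_edges))
        model = fit_plsr_components(sf_cohort.atrophy,
                                    sf_cohort.fc_edges[perm], 3)
        true_model = fit_plsr_components(sf_cohort.atrophy,
                                         sf_cohort.fc_edges, 3)
        assert np.all(np.abs(model.score_correlations_)
                      < np.abs(true_model.score_correlations_))

    def test_variance_explained_sums_below_one(self, sf_cohort):
        model = fit_plsr_components(sf_cohort.atrophy, sf_cohort.fc_edges, 3)
        ve = model.atrophy_variance_explained_
        assert np.all(ve >= 0) and ve.sum() <= 1.0
        assert ve[0] > ve[1] > ve[2]

    def test_too_many_components(self, rng):
        with pytest.raises(ValueError):
            fit_plsr_components(rng.normal(size=(10, 4)),
                                rng.normal(size=(10, 6)), 5)


class TestSplitHalf:
    def test_planted_components_reliable_noise_component_not(self, sf_cohort):
        res = split_half_reliability(sf_cohort.atrophy, sf_cohort.fc_edges,
                                     sf_cohort.labels, n_splits=30, seed=0,
                                     n_components=4)
        med = res["median_abs_r"]
        assert np.all(med[:3] > 0.9)
        assert med[3] < 0.5

    def test_deterministic_given_seed(self, sf_cohort):
        a = split_half_reliability(sf_cohort.atrophy, sf_cohort.fc_edges,
                                   sf_cohort.labels, n_splits=1, seed=42,
                                   n_components=2)
        b = split_half_reliability(sf_cohort.atrophy, sf_cohort.fc_edges,
                                   sf_cohort.labels, n_splits=1, seed=42,
                                   n_components=2)
        assert np.array_equal(a["loading_correlations"],
                              b["loading_correlations"])

    def test_singleton_label_rejected(self, rng):
        atrophy = rng.normal(size=(11, 5))
        fc = rng.normal(size=(11, 8))
        labels = np.array(["a"] * 10 + ["b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            split_half_reliability(atrophy, fc, labels, n_splits=1,
                                   n_components=2)


class TestAtrophyPCA:
    def test_matches_plsr_structure_loadings(self, sf_cohort):
        model = fit_plsr_components(sf_cohort.atrophy, sf_cohort.fc_edges, 3)
        _, loadings = atrophy_pca_scores(sf_cohort.atrophy, 3)
        for c in range(3):
            r = np.corrcoef(loadings[:, c],
                            model.structure_loadings_[:, c])[0, 1]
            assert abs(r) > 0.95

    def test_orthogonal_patterns_in_variance_order(self, rng):
        F = rng.normal(size=(100, 2)) * [3.0, 1.0]
        P = np.linalg.qr(rng.normal(size=(12, 2)))[0]
        X = F @ P.T
        _, loadings = atrophy_pca_scores(X, 2)
        assert abs(loadings[:, 0] @ P[:, 0]) > 0.99
        assert abs(loadings[:, 1] @ P[:, 1]) > 0.99

    def test_full_rank_round_trip(self, rng):
        X = rng.normal(size=(30, 6))
        scores, loadings = atrophy_pca_scores(X, 6)
        assert np.allclose(scores @ loadings.T, X - X.mean(axis=0), atol=1e-10)


class TestRidgeScores:
    def test_out_of_fold_r_near_planted_coupling(self, sf_cohort):
        scores, _ = atrophy_pca_scores(sf_cohort.atrophy, 3)
        _, _, fold_r = ridge_function_scores(
            scores, sf_cohort.fc_edges, alpha=1000.0, n_trials=3,
            labels=sf_cohort.labels, seed=0,
        )
        assert abs(np.nanmedian(fold_r) - 0.6) < 0.2

    def test_no_leakage_under_row_shuffle(self, sf_cohort, rng):
        """Out-of-fold scores carry no information when FC rows are shuffled
        relative to the atrophy scores."""
        scores, _ = atrophy_pca_scores(sf_cohort.atrophy, 3)
        shuffled = sf_cohort.fc_edges[rng.permutation(len(scores))]
        _, _, fold_r = ridge_function_scores(
            scores, shuffled, alpha=1000.0, n_trials=3,
            labels=sf_cohort.labels, seed=0,
        )
        assert abs(np.nanmedian(fold_r)) < 0.15

    def test_stratification_error_for_sparse_label(self, rng):
        scores = rng.normal(size=(20, 2))
        fc = rng.normal(size=(20, 30))
        labels = np.array(["a"] * 18 + ["b"] * 2)
        with pytest.raises(ValueError, match="stratification"):
            ridge_function_scores(scores, fc, n_folds=4, labels=labels)


class TestReconstruction:
    def test_zero_scores_zero_vector(self, rng):
        L = rng.normal(size=(15, 3))
        assert np.allclose(reconstruct_fc_from_components(np.zeros(3), L), 0)

    def test_one_hot_selects_loading_column(self, rng):
        L = rng.normal(size=(15, 3))
        assert np.allclose(reconstruct_fc_from_components([0, 1, 0], L),
                           L[:, 1])

    def test_full_rank_reconstruction_on_noise_free_cohort(self, rng):
        F = rng.normal(size=(50, 3))
        Q = rng.normal(size=(40, 3))
        edges = F @ Q.T
        atrophy = F @ rng.normal(size=(12, 3)).T
        model = fit_plsr_components(atrophy, edges, 3)
        recon = reconstruct_fc_from_components(model.structure_scores_,
                                               model.function_loadings_)
        centered = edges - edges.mean(axis=0)
        assert np.max(np.abs(recon - centered)) < 1e-8

    def test_group_difference_reconstruction(self, sf_cohort):
        """Mean FC difference of high- vs low-severity subjects is captured
        by the component reconstruction."""
        model = fit_plsr_components(sf_cohort.atrophy, sf_cohort.fc_edges, 3)
        s1 = model.structure_scores_[:, 0]
        hi = s1 > np.quantile(s1, 2 / 3)
        lo = s1 < np.quantile(s1, 1 / 3)
        actual = sf_cohort.fc_edges[hi].mean(axis=0) - sf_cohort.fc_edges[lo].mean(axis=0)
        recon = reconstruct_fc_from_components(
            model.structure_scores_[hi].mean(axis=0)
            - model.structure_scores_[lo].mean(axis=0),
            model.function_loadings_,
        )
        assert np.corrcoef(actual, recon)[0, 1] > 0.9


class TestNetworkSummary:
    def test_uniform_edges(self):
        vec = np.ones(6)      # R = 4
        assert np.allclose(network_summary_map(vec), 3.0)

    def test_single_edge(self):
        vec = np.zeros(6)
        vec[1] = 2.5          # edge (0, 2) in row-major upper triangle
        summary = network_summary_map(vec)
        assert summary[0] == summary[2] == 2.5
        assert summary[1] == summary[3] == 0.0

    def test_matches_dense_row_sums(self, rng):
        m = rng.normal(size=(9, 9))
        m = m + m.T
        np.fill_diagonal(m, 0.0)
        assert np.allclose(network_summary_map(edge_vector(m)),
                           m.sum(axis=1), atol=1e-12)

    def test_bad_length(self):
        with pytest.raises(ValueError):
            network_summary_map(np.ones(7))


class TestMDS:
    def test_planar_input_preserved(self, rng):
        X = np.column_stack([rng.normal(size=(20, 2)), np.full(20, 3.0)])
        res = mds_embed(X)
        emb = res["embedding"]
        d_in = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        d_out = np.linalg.norm(emb[:, None] - emb[None, :], axis=2)
        assert np.max(np.abs(d_in - d_out)) < 1e-8

    def test_equilateral_triangle(self):
        X = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        emb = mds_embed(X)["embedding"]
        d = np.linalg.norm(emb[:, None] - emb[None, :], axis=2)
        side = d[0, 1]
        assert d[0, 2] == pytest.approx(side, abs=1e-8)
        assert d[1, 2] == pytest.approx(side, abs=1e-8)

    def test_random_cloud_distance_correlation(self, rng):
        res = mds_embed(rng.normal(size=(40, 3)))
        assert res["distance_correlation"] > 0.8

    def test_degenerate_input(self):
        with pytest.raises(ValueError, match="degenerate"):
            mds_embed(np.ones((5, 3)))


class TestTypicalPatientsLDA:
    def test_separated_clusters_all_typical(self, rng):
        X = np.vstack([rng.normal(size=(20, 3)) + [10, 0, 0],
                       rng.normal(size=(20, 3)) - [10, 0, 0]])
        labels = np.array(["a"] * 20 + ["b"] * 20)
        res = typical_patients_lda(X, labels)
        assert res["typical"].all()
        assert res["counts"]["a"]["typical"] == 20

    def test_identical_distributions_near_chance(self, rng):
        X = rng.normal(size=(200, 3))
        labels = np.array(["a", "b"] * 100)
        res = typical_patients_lda(X, labels)
        rate = res["typical"].mean()
        assert 0.35 < rate < 0.75

    def test_deterministic(self, rng):
        X = rng.normal(size=(30, 3))
        labels = np.array(["a"] * 15 + ["b"] * 15)
        a = typical_patients_lda(X, labels)
        b = typical_patients_lda(X, labels)
        assert np.array_equal(a["typical"], b["typical"])

    def test_tiny_label_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        labels = np.array(["a"] * 7 + ["b"] * 3)
        with pytest.raises(ValueError):
            typical_patients_lda(X, labels)
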