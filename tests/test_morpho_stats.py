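"""Feature screening, PCA, k-means elbow, and the nested-CV classifier."""

import numpy as np
import pandas as pd
import pytest

from mglia.features import SIGNIFICANT_FEATURES
from mglia.morpho_stats import (
    cluster_composition,
    elbow_select_k,
    feature_significance,
    gain_importance,
    gbt_nested_cv,
    kmeans_fit,
    pca_project,
    select_k_from_curve,
)
from mglia.synthetic import MorphoPopulationSpec, disease_effects, simulate_morphology_table

ONE_POINT_GRID = {
    "n_estimators": [100],
    "learning_rate": [0.1],
    "max_depth": [2],
    "colsample_bytree": [1.0],
}


def two_group_frame(n=100, p=10, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n, p))
    b = rng.normal(0, 1, (n, p))
    b[:, 0] += shift
    df = pd.DataFrame(np.vstack([a, b]), columns=[f"f{i}" for i in range(p)])
    df["genotype"] = np.repeat(["WT", "MJD"], n)
    return df


class TestSignificance:
    def test_identical_groups_p_one(self):
        rng = np.random.default_rng(0)
        block = rng.normal(size=(30, 4))
        df = pd.DataFrame(np.vstack([block, block]), columns=list("abcd"))
        df["genotype"] = np.repeat(["WT", "MJD"], 30)
        rep = feature_significance(df)
        assert np.allclose(rep.p_value, 1.0)

    def test_planted_shift_detected(self):
        rep = feature_significance(two_group_frame(n=300, shift=3.0, seed=1))
        assert rep.set_index("feature").loc["f0", "p_value"] < 1e-6

    def test_constant_feature_warns_and_reports_one(self):
        df = two_group_frame(n=20, seed=2)
        df["flat"] = 1.0
        with pytest.warns(UserWarning, match="flat"):
            rep = feature_significance(df)
        assert rep.set_index("feature").loc["flat", "p_value"] == 1.0
        assert not rep.set_index("feature").loc["flat", "selected"]

    def test_selected_iff_below_alpha(self):
        rep = feature_significance(two_group_frame(n=200, shift=1.0, seed=3), alpha=0.05)
        assert ((rep.p_value < 0.05) == rep.selected).all()

    def test_more_than_two_groups_rejected(self):
        df = two_group_frame(n=10)
        df.loc[0, "genotype"] = "other"
        with pytest.raises(ValueError, match="two groups"):
            feature_significance(df)


class TestPCA:
    def test_planar_data_needs_two_components(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 14))
        coords = rng.normal(size=(200, 2))
        res = pca_project(coords @ basis, standardize=False)
        assert res.cumulative_fraction(2) == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_gaussian_spreads_evenly(self):
        rng = np.random.default_rng(1)
        res = pca_project(rng.normal(size=(10_000, 14)))
        assert np.allclose(res.variance_fraction, 1 / 14, atol=0.01)

    def test_variance_fractions_valid(self):
        rng = np.random.default_rng(2)
        res = pca_project(rng.normal(size=(50, 5)) * [5, 3, 2, 1, 1])
        vf = res.variance_fraction
        assert (vf >= 0).all()
        assert (np.diff(vf) <= 1e-12).all()
        assert vf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_column_keeps_total_variance_complete(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(100, 5))
        x_dup = np.hstack([x, x[:, :1]])
        res = pca_project(x_dup)
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)


class TestKMeans:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(100, 3))
        labels, centers, mse = kmeans_fit(x, 1)
        assert np.allclose(centers[0], x.mean(axis=0))
        assert mse == pytest.approx(((x - x.mean(0)) ** 2).sum(1).mean())

    def test_separated_blobs_pure(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(0, 1, (50, 4)), rng.normal(10, 1, (60, 4))])
        labels, _, _ = kmeans_fit(x, 2, seed=1)
        first, second = labels[:50], labels[50:]
        assert len(set(first)) == 1 and len(set(second)) == 1 and first[0] != second[0]

    def test_k_equals_n_zero_mse(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(8, 2))
        _, _, mse = kmeans_fit(x, 8, seed=0)
        assert mse == pytest.approx(0.0, abs=1e-12)

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans_fit(np.zeros((3, 2)), 4)

    def test_mse_non_increasing_in_k(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(200, 5))
        mse = [kmeans_fit(x, k, n_restarts=10, seed=0)[2] for k in range(1, 9)]
        assert all(mse[i + 1] <= mse[i] + 1e-9 for i in range(len(mse) - 1))


class TestElbow:
    def test_two_phenotype_table_selects_two_clusters(self):
        hits = 0
        for seed in range(1, 11):
            table, _ = simulate_morphology_table(
                MorphoPopulationSpec(effects=disease_effects(3.0), seed=seed)
            )
            x = table[list(SIGNIFICANT_FEATURES)].to_numpy()
            for rule in ("knee", "largest_drop"):
                hits += elbow_select_k(x, rule=rule, seed=seed).chosen_k == 2
        assert hits >= 19  # both rules, ≥95% of seeds

    def test_four_separated_blobs_knee_finds_four(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            centers = rng.normal(0, 8, (4, 14))
            x = np.vstack([rng.normal(c, 1, (150, 14)) for c in centers])
            hits += elbow_select_k(x, rule="knee", seed=seed).chosen_k == 4
        assert hits >= 18  # ≥90% of seeds

    def test_geometric_curve_low_confidence(self):
        mse = [0.7**k for k in range(1, 13)]
        for rule in ("knee", "largest_drop"):
            curve = select_k_from_curve(mse, rule=rule)
            assert curve.chosen_k == 2
            assert curve.low_confidence

    def test_non_finite_curve_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            select_k_from_curve([4.0, np.nan, 1.0, 0.5])

    def test_small_k_max_rejected(self):
        with pytest.raises(ValueError):
            elbow_select_k(np.zeros((10, 2)), k_max=2)


class TestComposition:
    def test_separated_phenotypes_dominate_their_clusters(self):
        table, _ = simulate_morphology_table(
            MorphoPopulationSpec(n_per_group=(150, 150), effects=disease_effects(3.0), seed=0)
        )
        from sklearn.preprocessing import StandardScaler

        x = StandardScaler().fit_transform(table[list(SIGNIFICANT_FEATURES)])
        labels, _, _ = kmeans_fit(x, 2, seed=0)
        comp = cluster_composition(labels, table.genotype.to_numpy())
        assert (comp.max(axis=1) >= 0.95).all()

    def test_shuffled_labels_match_prior(self):
        rng = np.random.default_rng(0)
        assignments = rng.integers(0, 2, 600)
        labels = np.array(["A"] * 180 + ["B"] * 420)
        rng.shuffle(labels)
        comp = cluster_composition(assignments, labels)
        assert np.allclose(comp["A"], 0.3, atol=0.08)

    def test_single_cluster_recovers_global_proportions(self):
        labels = np.array(["A"] * 30 + ["B"] * 70)
        comp = cluster_composition(np.zeros(100, dtype=int), labels)
        assert comp.loc[0, "A"] == pytest.approx(0.3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cluster_composition([0, 1], ["A"])


class TestNestedCV:
    def test_coin_flip_labels_score_at_chance(self):
        accs = []
        for trial in range(4):
            rng = np.random.default_rng(trial)
            df = pd.DataFrame(rng.normal(size=(400, 10)), columns=[f"f{i}" for i in range(10)])
            labels = np.repeat(["WT", "MJD"], 200)
            rng.shuffle(labels)
            df["genotype"] = labels
            rep = gbt_nested_cv(df, grid=ONE_POINT_GRID, seed=trial)
            accs.append(rep.fold_metrics.accuracy.mean())
        assert 0.45 <= float(np.mean(accs)) <= 0.55

    def test_single_informative_feature_separates(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(400, 10)), columns=[f"f{i}" for i in range(10)])
        df["genotype"] = np.where(df["f3"] > 0, "MJD", "WT")
        rep = gbt_nested_cv(df, grid=ONE_POINT_GRID, seed=0)
        assert rep.fold_metrics.accuracy.mean() >= 0.95
        ranked = gain_importance(rep)
        assert ranked.index[0] == "f3"
        assert ranked.iloc[0] >= 0.8

    def test_importance_normalized(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(120, 6)), columns=[f"f{i}" for i in range(6)])
        df["genotype"] = np.where(df["f0"] + df["f1"] > 0, "a", "b")
        rep = gbt_nested_cv(df, grid=ONE_POINT_GRID, seed=1)
        assert rep.importance.sum() == pytest.approx(1.0, abs=1e-9)
        assert (rep.importance >= 0).all()

    def test_all_noise_importance_stays_diffuse(self):
        exceed = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(rng.normal(size=(500, 25)), columns=[f"f{i}" for i in range(25)])
            df["genotype"] = np.repeat(["WT", "MJD"], 250)
            rep = gbt_nested_cv(df, grid=ONE_POINT_GRID, seed=seed)
            exceed += gain_importance(rep).iloc[0] > 3 / 25
        assert exceed <= 1

    def test_tiny_dataset_runs(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        df["genotype"] = ["x", "y"] * 5
        rep = gbt_nested_cv(df, grid=ONE_POINT_GRID, outer=5, inner=2, seed=0)
        assert len(rep.fold_metrics) == 5

    def test_grid_selection_prefers_parsimony_on_ties(self):
        # perfectly separable: every grid point scores 1.0, so the
        # parsimony order must pick the smallest model
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        df["genotype"] = np.where(df["a"] > 0, "x", "y")
        grid = {"n_estimators": [50, 100], "learning_rate": [0.1], "max_depth": [2, 3], "colsample_bytree": [1.0]}
        rep = gbt_nested_cv(df, grid=grid, seed=0)
        assert all(p["n_estimators"] == 50 and p["max_depth"] == 2 for p in rep.selected_params)

    def test_non_binary_label_rejected(self):
        df = two_group_frame(n=10)
        df.loc[0, "genotype"] = "third"
        with pytest.raises(ValueError, match="binary"):
            gbt_nested_cv(df, grid=ONE_POINT_GRID)
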