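"""RPM, differential expression, overlap statistics, qPCR fold changes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mglia.gene_sets import MJD_VS_AD, MJD_VS_ALS, MARKER_PANELS, GeneSet
from mglia.synthetic import CountSimSpec, planted_spec_at_study_scale, simulate_count_matrix
from mglia.transcriptomics import (
    baptista_pike_ci,
    classify_shared_genes,
    ddct_fold_change,
    differential_expression,
    direction_concordance,
    filter_degs,
    fisher_exact_table,
    fisher_overlap,
    marker_panel_scores,
    rpm_normalize,
    signed_fold_change,
)


class TestRPM:
    def test_single_gene_saturates(self):
        counts = pd.DataFrame({"s1": [5], "s2": [50]}, index=["g"])
        rpm = rpm_normalize(counts)
        assert np.allclose(rpm.to_numpy(), 1e6)

    def test_proportions_preserved(self):
        counts = pd.DataFrame({"s1": [3, 1]}, index=["a", "b"])
        rpm = rpm_normalize(counts)
        assert rpm.loc["a", "s1"] == pytest.approx(750_000)
        assert rpm.loc["b", "s1"] == pytest.approx(250_000)

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 1000, (200, 6)))
        counts.iloc[0] += 1  # ensure no zero-total column
        rpm = rpm_normalize(counts)
        assert np.allclose(rpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_total_sample_named(self):
        counts = pd.DataFrame({"ok": [1, 2], "empty": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            rpm_normalize(counts)


class TestFoldChange:
    def test_signed_convention(self):
        fc = signed_fold_change(np.array([10.0, 5.0, 5.0]), np.array([5.0, 10.0, 5.0]))
        assert fc[0] == pytest.approx(2.0)
        assert fc[1] == pytest.approx(-2.0)
        assert fc[2] == pytest.approx(1.0)
        assert np.all(np.abs(fc) >= 1.0)


def _de_run(spec: CountSimSpec, method="moderated"):
    counts, groups, truth = simulate_count_matrix(spec)
    rpm = rpm_normalize(counts)
    return differential_expression(rpm, groups, method=method), truth


class TestDifferentialExpression:
    def test_null_fold_changes_near_one_p_uniform(self):
        spec = CountSimSpec(
            n_genes=2000, n_per_group=(20, 20), baseline_log_mean=np.log(500),
            baseline_log_sd=1.0, seed=0,
        )
        table, _ = _de_run(spec)
        assert table.fold_change.abs().median() < 1.2
        assert 0.4 < table.p_value.mean() < 0.6

    @pytest.mark.parametrize("method", ["moderated", "welch"])
    def test_planted_four_fold_gene_passes_filter(self, method):
        hits = 0
        sims = 30
        for seed in range(sims):
            spec = CountSimSpec(
                n_genes=500, planted_up=frozenset({7}), log2_effect=2.0,
                nb_dispersion=0.05, baseline_log_mean=np.log(500),
                baseline_log_sd=0.8, seed=seed,
            )
            table, _ = _de_run(spec, method=method)
            up, down = filter_degs(table)
            hits += "gene00007" in up.index
        # the moderated test recovers essentially always; Welch at n=4 has
        # little power at BH-corrected thresholds and is not asserted here
        if method == "moderated":
            assert hits >= 0.95 * sims

    def test_all_zero_gene_flagged_untested(self):
        counts = pd.DataFrame(
            {"a1": [0, 5], "a2": [0, 8], "b1": [0, 9], "b2": [0, 4]}, index=["dead", "ok"]
        )
        groups = pd.Series(["A", "A", "B", "B"], index=counts.columns)
        rpm = counts * (1e6 / counts.sum(0))
        table = differential_expression(rpm, groups)
        assert not table.loc["dead", "tested"]
        assert np.isnan(table.loc["dead", "p_value"])
        assert table.loc["dead", "direction"] == "undefined"

    def test_bh_correction_matches_hand_computation(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        fdr = stats.false_discovery_control(p, method="bh")
        assert np.allclose(fdr, [0.04, 0.04, 0.04, 0.04])
        # monotone non-decreasing along sorted p-values
        rng = np.random.default_rng(0)
        p = rng.random(100)
        fdr = stats.false_discovery_control(np.sort(p), method="bh")
        assert (np.diff(fdr) >= -1e-12).all()

    def test_missing_group_sample_rejected(self):
        counts = pd.DataFrame(np.ones((3, 4)), columns=["a", "b", "c", "d"])
        groups = pd.Series(["x", "x", "y"], index=["a", "b", "c"])
        with pytest.raises(ValueError, match="d"):
            differential_expression(counts, groups)


class TestDegFilter:
    def test_identical_means_excluded_at_literal_threshold(self):
        counts = pd.DataFrame(
            {"a1": [10, 30], "a2": [10, 10], "b1": [10, 20], "b2": [10, 7]},
            index=["flat", "varies"],
        )
        groups = pd.Series(["A", "A", "B", "B"], index=counts.columns)
        table = differential_expression(counts.astype(float), groups)
        up, down = filter_degs(table, fc_threshold=1.0)
        assert "flat" not in up.index and "flat" not in down.index

    def test_null_simulation_passes_almost_nothing(self):
        spec = CountSimSpec(n_genes=5000, seed=11)  # no planted signal
        table, _ = _de_run(spec)
        up, down = filter_degs(table)
        assert len(up) + len(down) <= 5

    def test_study_scale_recovery(self):
        """Planted 83 up + 18 down at |log2FC| = 2 are recovered near the
        planted counts by the |FC|>1 ∧ p<0.05 ∧ FDR<0.1 filter."""
        spec = planted_spec_at_study_scale(seed=1)
        table, truth = _de_run(spec)
        up, down = filter_degs(table)
        assert 70 <= len(up) <= 95
        assert 12 <= len(down) <= 24

    def test_planted_truth_sensitivity_and_fdr(self):
        """Across seeds: sensitivity ≥ 0.9 for planted genes and observed
        FDR ≤ ≈0.1 among reported DEGs."""
        sens, fdps = [], []
        for seed in range(5):
            spec = planted_spec_at_study_scale(seed)
            table, truth = _de_run(spec)
            up, down = filter_degs(table)
            called = set(up.index) | set(down.index)
            planted = set(truth.loc[truth.status != "null", "gene"])
            tp = len(called & planted)
            sens.append(tp / len(planted))
            fdps.append((len(called) - tp) / max(1, len(called)))
        assert float(np.mean(sens)) >= 0.85
        assert float(np.mean(fdps)) <= 0.12


class TestFisherOverlap:
    def test_symmetric_table(self):
        assert fisher_exact_table(5, 5, 5, 5) == pytest.approx(1.0)
        a, b = GeneSet("A", ("g1", "g2")), GeneSet("B", ("g1", "g3"))
        res = fisher_overlap(a, b, universe_size=4)
        assert res.table == (1, 1, 1, 1)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_exhaustive_enumeration_small_margins(self):
        """Fisher p equals brute-force minimum-likelihood hypergeometric
        enumeration for every table with margins ≤ 8 (spot check; the
        full ≤ 12 sweep runs in the acceptance suite)."""
        def brute(a, b, c, d):
            r1, c1, n = a + b, a + c, a + b + c + d
            lo, hi = max(0, r1 + c1 - n), min(r1, c1)
            pmf = np.array([stats.hypergeom.pmf(x, n, c1, r1) for x in range(lo, hi + 1)])
            return float(pmf[pmf <= pmf[a - lo] * (1 + 1e-9)].sum())

        for a in range(9):
            for b in range(9 - a):
                for c in range(9 - a):
                    for d in range(9):
                        if a + b + c + d == 0 or b + d > 8 or c + d > 8:
                            continue
                        assert abs(fisher_exact_table(a, b, c, d) - brute(a, b, c, d)) < 1e-10

    def test_universe_smaller_than_union_rejected(self):
        a = GeneSet("A", tuple(f"g{i}" for i in range(30)))
        b = GeneSet("B", tuple(f"h{i}" for i in range(30)))
        with pytest.raises(ValueError, match="universe"):
            fisher_overlap(a, b, universe_size=50)

    def test_ci_contains_point_estimate(self):
        res_low, res_high = baptista_pike_ci(8, 2, 1, 9)
        assert res_low < 36.0 < res_high

    def test_ci_coverage_near_nominal(self):
        """The 95% Baptista–Pike interval covers the true odds ratio at
        ≈ nominal rate under conditional sampling at fixed margins."""
        rng = np.random.default_rng(0)
        n, r1, c1, psi = 40, 15, 20, 3.0
        cover = 0
        reps = 200
        draws = stats.nchypergeom_fisher.rvs(n, c1, r1, psi, size=reps, random_state=rng)
        for a in draws:
            a = int(a)
            lo, hi = baptista_pike_ci(a, r1 - a, c1 - a, n - r1 - c1 + a)
            cover += lo <= psi <= hi
        assert 0.90 <= cover / reps <= 0.995

    def test_zero_cell_gives_one_sided_infinite_bound(self):
        lo, hi = baptista_pike_ci(5, 0, 2, 10)
        assert lo > 0 and np.isinf(hi)


class TestConcordance:
    def test_printed_als_comparison(self):
        assert direction_concordance(*MJD_VS_ALS) == (17, 10, 27)

    def test_printed_ad_comparison(self):
        assert direction_concordance(*MJD_VS_AD) == (12, 19, 31)

    def test_self_comparison_fully_concordant(self):
        a = MJD_VS_ALS[0]
        assert direction_concordance(a, a) == (len(a), 0, len(a))

    def test_disjoint_sets(self):
        a = GeneSet("A", ("x",), {"x": "up"})
        b = GeneSet("B", ("y",), {"y": "down"})
        assert direction_concordance(a, b) == (0, 0, 0)

    def test_missing_direction_names_gene(self):
        a = GeneSet("A", ("x", "y"), {"x": "up", "y": "down"})
        b = GeneSet("B", ("x", "y"))
        with pytest.raises(ValueError, match="direction"):
            direction_concordance(a, b)

    def test_case_insensitive_matching(self):
        a = GeneSet("A", ("Plin2",), {"Plin2": "down"})
        b = GeneSet("B", ("PLIN2",), {"PLIN2": "down"})
        assert direction_concordance(a, b) == (1, 0, 1)

    def test_per_gene_classification_table(self):
        df = classify_shared_genes(*MJD_VS_ALS)
        assert len(df) == 27
        assert df.concordant.sum() == 17


class TestMarkerPanels:
    def _rpm(self, microglia_level=100.0, other_level=1.0):
        genes = [g for panel in MARKER_PANELS.values() for g in panel]
        rng = np.random.default_rng(0)
        data = {}
        for s in ["s1", "s2"]:
            vals = []
            for panel, members in MARKER_PANELS.items():
                level = microglia_level if panel == "microglia" else other_level
                vals.extend(level * (1 + 0.01 * rng.random(len(members))))
            data[s] = vals
        return pd.DataFrame(data, index=genes)

    def test_enriched_profile_scores_high(self):
        scores, enrichment, misses = marker_panel_scores(self._rpm(), MARKER_PANELS)
        assert enrichment >= 50
        assert all(not m for m in misses.values())

    def test_uniform_profile_scores_one(self):
        scores, enrichment, _ = marker_panel_scores(self._rpm(1.0, 1.0), MARKER_PANELS)
        assert enrichment == pytest.approx(1.0, rel=0.05)

    def test_missing_symbols_reported(self):
        rpm = self._rpm().drop(index=["Tmem119"])
        scores, _, misses = marker_panel_scores(rpm, MARKER_PANELS)
        assert misses["microglia"] == ["Tmem119"]

    def test_unmatched_panel_rejected(self):
        rpm = pd.DataFrame({"s": [1.0]}, index=["Hexb"])
        with pytest.raises(ValueError, match="astrocyte"):
            marker_panel_scores(rpm, {"microglia": ("Hexb",), "astrocyte": ("Gfap",)})


class TestQpcr:
    def _ct(self, target_shift=0.0):
        rows = []
        for i, group in enumerate(["WT"] * 3 + ["MJD"] * 3):
            s = f"s{i}"
            rows.append({"sample": s, "group": group, "gene": "B2m", "CT": 20.0})
            ct = 25.0 - (target_shift if group == "MJD" else 0.0)
            rows.append({"sample": s, "group": group, "gene": "Fos", "CT": ct})
        return pd.DataFrame(rows)

    def test_equal_cts_give_unit_fold(self):
        out = ddct_fold_change(self._ct(), "Fos", "B2m", "WT")
        assert np.allclose(out.fold_change, 1.0)

    def test_one_cycle_lower_doubles(self):
        out = ddct_fold_change(self._ct(target_shift=1.0), "Fos", "B2m", "WT")
        assert np.allclose(out.loc[out.group == "MJD", "fold_change"], 2.0)

    def test_reference_group_centered_at_unit_fold(self):
        rng = np.random.default_rng(0)
        ct = self._ct()
        ct.loc[ct.gene == "Fos", "CT"] += rng.normal(0, 0.3, 6)
        out = ddct_fold_change(ct, "Fos", "B2m", "WT")
        ref = out.loc[out.group == "WT", "delta_delta_ct"]
        assert ref.mean() == pytest.approx(0.0, abs=1e-12)
        assert np.exp(np.log(out.loc[out.group == "WT", "fold_change"]).mean()) == pytest.approx(1.0)

    def test_missing_housekeeping_named(self):
        ct = self._ct().query("~(sample == 's2' and gene == 'B2m')")
        with pytest.raises(ValueError, match="s2"):
            ddct_fold_change(ct, "Fos", "B2m", "WT")
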