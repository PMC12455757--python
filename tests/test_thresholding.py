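"""Distribution diagnosis, threshold algorithms, validation, classification."""

import numpy as np
import pandas as pd
import pytest

from isoplex.thresholding import (
    LABELS,
    DistributionDiagnosis,
    bootstrap_threshold,
    classify_genes,
    detect_zero_inflation,
    diagnose_distribution,
    determine_threshold,
    dip_test,
    find_complexity_pattern,
    kfold_threshold_stability,
    reliability_score,
    sanity_check,
    threshold_with_validation,
)


def bimodal(rng, n=500, mu=(0.2, 0.8), sd=0.05):
    half = n // 2
    return np.concatenate([rng.normal(mu[0], sd, half), rng.normal(mu[1], sd, n - half)])


class TestDipTest:
    def test_separated_modes_rejected_unimodal_not(self):
        rng = np.random.default_rng(3)
        _, p_bim = dip_test(bimodal(rng))
        _, p_norm = dip_test(rng.normal(0, 1, 500))
        assert p_bim < 0.05
        assert p_norm > 0.05

    def test_deterministic(self):
        x = bimodal(np.random.default_rng(5))
        assert dip_test(x) == dip_test(x)


class TestDiagnosis:
    def test_two_gaussians_multimodal(self):
        d = diagnose_distribution(bimodal(np.random.default_rng(0)))
        assert d.dist_class == "multimodal"
        assert d.multimodal_votes["dip"] and d.multimodal_votes["kde"]
        assert d.gmm_k_by_bic >= 2

    def test_half_normal_skewed(self):
        x = np.abs(np.random.default_rng(1).normal(0, 1, 500))
        d = diagnose_distribution(x)
        assert d.dist_class in ("moderately_skewed", "extremely_skewed")
        assert d.skewness > 0.5

    def test_zero_inflated_mixture(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([np.zeros(300), rng.normal(0.5, 0.1, 200)])
        d = diagnose_distribution(x)
        assert d.dist_class == "zero_inflated"
        assert d.zero_inflation["inflated"]

    def test_constant_input_degenerate_unimodal(self):
        d = diagnose_distribution(np.full(100, 0.3))
        assert d.dist_class == "unimodal"
        assert "degenerate" in d.flags

    def test_small_sample_low_data_flag(self):
        d = diagnose_distribution(np.random.default_rng(0).normal(0, 1, 10))
        assert d.dist_class == "unimodal"
        assert "low_data" in d.flags


class TestZeroInflation:
    def test_positive_unimodal_not_inflated(self):
        x = np.random.default_rng(0).normal(5.0, 0.5, 500)
        assert not detect_zero_inflation(x)["inflated"]

    def test_extreme_zeros_inflated(self):
        x = np.concatenate([np.zeros(400), np.random.default_rng(0).uniform(0.5, 1, 100)])
        assert detect_zero_inflation(x)["inflated"]

    def test_cutoff_is_strict(self):
        from isoplex.thresholding import ThresholdConfig

        # engineer first/second bin ratio == exactly the cutoff -> not inflated
        cfg = ThresholdConfig(zero_bin_ratio=3.0)
        x = np.concatenate([np.full(30, 0.05), np.full(10, 0.55), np.full(10, 1.05), np.full(10, 1.55)])
        ev = detect_zero_inflation(x, cfg)
        if ev["first_second_bin_ratio"] == 3.0:
            assert not ev["inflated"]


class TestDetermineThreshold:
    def test_bimodal_valley_near_half(self):
        x = bimodal(np.random.default_rng(0))
        d = diagnose_distribution(x)
        thr, trace, used, rank = determine_threshold(x, d)
        assert abs(thr - 0.5) <= 0.05
        assert used == "kde_valley" and rank == "primary"

    def test_exponential_inside_central_band(self):
        x = np.random.default_rng(0).exponential(1.0, 500)
        d = diagnose_distribution(x)
        thr, *_ = determine_threshold(x, d)
        thr, _ = sanity_check(thr, x)
        p5, p95 = np.percentile(x, [5, 95])
        assert p5 < thr < p95

    def test_zero_inflated_gap_threshold_in_gap(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.uniform(0, 0.01, 300), rng.normal(0.7, 0.05, 200)])
        d = diagnose_distribution(x)
        thr, _, used, _ = determine_threshold(x, d)
        assert used == "zero_inflated_gap"
        assert 0.01 < thr < 0.55

    def test_terminal_fallback_always_yields_value(self):
        # force an impossible-class situation with a tiny weird sample
        x = np.array([0.1, 0.1, 0.1, 0.9])
        d = DistributionDiagnosis("multimodal", 0.01, 1, 1, 0.0, {}, {})
        thr, trace, used, rank = determine_threshold(x, d)
        assert np.isfinite(thr)
        assert x.min() <= thr <= x.max()

    def test_threshold_within_data_range(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.beta(2, 5, 200)
            d = diagnose_distribution(x)
            thr, *_ = determine_threshold(x, d)
            assert x.min() <= thr <= x.max()


class TestSanityCheck:
    def test_extreme_clamped_and_idempotent(self):
        x = np.random.default_rng(0).normal(0, 1, 500)
        hi = np.percentile(x, 99.9)
        clamped, adjusted = sanity_check(hi, x)
        assert adjusted
        assert clamped == pytest.approx(np.percentile(x, 95))
        again, adj2 = sanity_check(clamped, x)
        assert again == clamped and not adj2

    def test_median_unchanged(self):
        x = np.random.default_rng(0).normal(0, 1, 500)
        thr, adjusted = sanity_check(np.median(x), x)
        assert not adjusted


class TestBootstrapAndKfold:
    def test_default_iterations_and_determinism(self):
        x = bimodal(np.random.default_rng(0))
        d = diagnose_distribution(x)
        b1 = bootstrap_threshold(x, d, seed=9)
        b2 = bootstrap_threshold(x, d, seed=9)
        assert b1["n_iter"] == 100
        assert b1 == b2

    def test_constant_data_sd_zero_cv_na(self):
        x = np.full(60, 0.4)
        d = diagnose_distribution(x)
        b = bootstrap_threshold(x, d, n_iter=20, seed=0)
        assert b["sd"] == 0.0
        assert np.isnan(b["cv"])

    def test_kfold_insufficient_sample_na(self):
        x = np.random.default_rng(0).normal(0, 1, 30)
        d = diagnose_distribution(x)
        assert np.isnan(kfold_threshold_stability(x, d, k=5))

    def test_kfold_stable_on_clean_bimodal(self):
        x = bimodal(np.random.default_rng(4))
        d = diagnose_distribution(x)
        cv = kfold_threshold_stability(x, d, k=5, seed=0)
        b = bootstrap_threshold(x, d, seed=0)
        assert cv < (b["cv"] if np.isfinite(b["cv"]) else 0.0) + 0.1


class TestReliability:
    def _diag(self, flags=()):
        return DistributionDiagnosis("unimodal", 0.5, 1, 1, 0.0, {}, {}, flags=list(flags))

    def test_primary_low_cv_high_score(self):
        s = reliability_score("primary", self._diag(), {"cv": 0.01}, 0.01)
        assert s >= 0.9

    def test_terminal_fallback_low_score(self):
        s = reliability_score("terminal", self._diag(), {"cv": 0.0}, np.nan)
        assert s <= 0.5

    def test_monotone_in_bootstrap_cv(self):
        prev = 1.1
        for cv in (0.0, 0.1, 0.3, 0.8):
            s = reliability_score("primary", self._diag(), {"cv": cv}, np.nan)
            assert s <= prev
            prev = s

    def test_problem_flags_penalize(self):
        base = reliability_score("primary", self._diag(), {"cv": 0.0}, np.nan)
        flagged = reliability_score("primary", self._diag(["n<50"]), {"cv": 0.0}, np.nan)
        assert flagged == pytest.approx(0.8 * base)


class TestClassification:
    @pytest.fixture()
    def metrics_df(self):
        return pd.DataFrame(
            {
                "idi_intra": [0.9, 0.1, np.nan],
                "idi_inter": [0.8, 0.2, 0.5],
                "het": [0.7, 0.2, 0.3],
                "spec": [0.9, np.nan, 0.1],
                "het_var": [0.5, 0.1, np.nan],
                "diff_var": [0.6, 0.1, np.nan],
                "coexp_var": [0.4, 0.1, np.nan],
            },
            index=["gA", "gB", "gC"],
        )

    def test_labels_and_na_preserved(self, metrics_df):
        thr = {m: 0.45 for m in LABELS}
        labels = classify_genes(metrics_df, thr)
        assert labels.loc["gA", "idi_intra"] == "Strong Isoform Co-expression"
        assert labels.loc["gB", "idi_intra"] == "Weak Isoform Co-expression"
        assert labels.loc["gA", "spec"] == "Cell-Type-Specific Isoform Expression"
        assert labels.loc["gB", "spec"] is None  # NA preserved
        assert labels.loc["gA"].notna().all()  # all seven labels emitted

    def test_inclusive_boundary_and_monotonicity(self, metrics_df):
        thr = {m: 0.5 for m in LABELS}
        labels = classify_genes(metrics_df.assign(idi_inter=[0.5, 0.2, 0.5]), thr)
        assert labels.loc["gA", "idi_inter"] == "High Isoform Diversity"  # == threshold
        # raising a value never flips high -> low
        bumped = classify_genes(metrics_df.assign(idi_inter=[0.95, 0.2, 0.5]), thr)
        assert bumped.loc["gA", "idi_inter"] == "High Isoform Diversity"

    def test_missing_threshold_warns_and_skips(self, metrics_df):
        with pytest.warns(UserWarning, match="spec"):
            labels = classify_genes(metrics_df, {m: 0.5 for m in LABELS if m != "spec"})
        assert "spec" not in labels.columns

    def test_find_pattern_matches_bruteforce(self, metrics_df):
        thr = {m: 0.45 for m in LABELS}
        labels = classify_genes(metrics_df, thr)
        pattern = {
            "idi_inter": "High Isoform Diversity",
            "spec": "Cell-Type-Specific Isoform Expression",
        }
        got = find_complexity_pattern(labels, pattern)
        expected = [
            g for g in labels.index
            if all(labels.loc[g, k] == v for k, v in pattern.items())
        ]
        assert got == expected == ["gA"]
        assert find_complexity_pattern(labels, {}) == list(labels.index)
        with pytest.raises(KeyError):
            find_complexity_pattern(labels, {"nonsense": "x"})


class TestRecoveryProperty:
    def test_threshold_recovery_across_seeds(self):
        # 50/50 mixture at 0.2/0.8 with sigma 0.05: analytic valley at 0.5
        hits = 0
        for seed in range(10):
            x = bimodal(np.random.default_rng(1000 + seed))
            res = threshold_with_validation(x, "m", n_boot=30, seed=seed)
            hits += abs(res.threshold - 0.5) <= 0.05
        assert hits >= 9
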