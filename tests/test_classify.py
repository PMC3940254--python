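import numpy as np
import pandas as pd
import pytest

from tumorline.classify import (
    IHC_PARAMETERS,
    CVScheme,
    compare_models,
    evaluate_model,
    fit_forest,
    make_cv_scheme,
    median_impute,
    parameter_importance,
    subset_sweep,
)
from conftest import make_noise_table, make_separable_table


def chance_band_99(n_classes, n_samples):
    """99% normal band around uniform chance, on the accuracy-% scale."""
    p = 1.0 / n_classes
    half = 2.576 * np.sqrt(p * (1 - p) / n_samples)
    return 100 * max(0.0, p - half), 100 * (p + half)


class TestMedianImpute:
    def test_simple_median(self):
        table = pd.DataFrame({"sample_id": list("abcd"), "line": list("xxyy"),
                              "v": [1.0, 2.0, np.nan, 4.0]})
        out = median_impute(table)
        assert out["v"].tolist() == [1.0, 2.0, 2.0, 4.0]

    def test_no_missing_is_identity(self):
        table = pd.DataFrame({"sample_id": list("abcd"), "line": list("xxyy"),
                              "v": [1.0, 2.0, 3.0, 4.0]})
        pd.testing.assert_frame_equal(median_impute(table), table)

    def test_two_missing_same_fill(self):
        table = pd.DataFrame({"sample_id": list("abcd"), "line": list("xxyy"),
                              "v": [1.0, 3.0, np.nan, np.nan]})
        out = median_impute(table)
        assert out["v"].tolist() == [1.0, 3.0, 2.0, 2.0]

    def test_observed_cells_unchanged(self, paper_cohort):
        table, _ = paper_cohort
        out = median_impute(table)
        mask = table.notna()
        for col in table.columns:
            assert (out.loc[mask[col], col] == table.loc[mask[col], col]).all()
        assert not out.drop(columns=["sample_id", "line"]).isna().any().any()

    def test_fully_missing_column_rejected(self):
        table = pd.DataFrame({"sample_id": list("ab"), "line": list("xy"),
                              "v": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="fully missing"):
            median_impute(table)


class TestFitForest:
    def test_separable_high_oob(self):
        table = make_separable_table(seed=0)
        _, oob = fit_forest(table, [f"p{j}" for j in range(9)], n_trees=300, seed=0)
        assert oob > 95.0

    def test_noise_oob_at_chance(self):
        table = make_noise_table(seed=1)
        _, oob = fit_forest(table, [f"p{j}" for j in range(9)], n_trees=500, seed=0)
        lo, hi = chance_band_99(14, 70)
        assert lo <= oob <= hi

    def test_single_class_rejected(self):
        table = make_noise_table(n_lines=2, seed=0)
        table["line"] = "L01"
        with pytest.raises(ValueError, match="two classes"):
            fit_forest(table, ["p0"], n_trees=10)

    def test_empty_columns_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_forest(make_noise_table(seed=0), [], n_trees=10)

    def test_missing_values_rejected(self):
        table = make_noise_table(seed=0)
        table.loc[0, "p0"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_forest(table, ["p0", "p1"], n_trees=10)


class TestCVScheme:
    def test_split_sizes_75_25(self):
        table = make_noise_table(n_lines=12, n_per_line=6, seed=0)  # 72 samples
        scheme = make_cv_scheme(table, n_repeats=5, seed=0)
        for train, test in scheme.splits:
            assert len(train) == 54 and len(test) == 18
            assert len(np.intersect1d(train, test)) == 0
            assert len(np.union1d(train, test)) == 72

    def test_same_seed_identical(self):
        table = make_noise_table(seed=0)
        a = make_cv_scheme(table, n_repeats=20, seed=3)
        b = make_cv_scheme(table, n_repeats=20, seed=3)
        assert a.fingerprint() == b.fingerprint()
        c = make_cv_scheme(table, n_repeats=20, seed=4)
        assert a.fingerprint() != c.fingerprint()

    def test_repeats_are_distinct_splits(self):
        table = make_noise_table(seed=0)
        scheme = make_cv_scheme(table, n_repeats=50, seed=0)
        fingerprints = {tuple(train.tolist()) for train, _ in scheme.splits}
        assert len(fingerprints) > 45  # collisions possible but rare

    def test_stratified_covers_every_line(self):
        table = make_noise_table(n_lines=14, n_per_line=5, seed=0)
        scheme = make_cv_scheme(table, n_repeats=30, seed=0, stratified=True)
        lines = table["line"].to_numpy()
        for train, _ in scheme.splits:
            assert len(np.unique(lines[train])) == 14

    def test_unstratified_mode(self):
        table = make_noise_table(seed=0)
        scheme = make_cv_scheme(table, n_repeats=10, seed=0, stratified=False)
        for train, test in scheme.splits:
            assert len(train) + len(test) == len(table)

    def test_json_round_trip(self):
        table = make_noise_table(seed=0)
        scheme = make_cv_scheme(table, n_repeats=7, seed=1)
        restored = CVScheme.from_json(scheme.to_json())
        assert restored.fingerprint() == scheme.fingerprint()
        assert restored.n_repeats == 7

    def test_invalid_train_fraction(self):
        table = make_noise_table(seed=0)
        with pytest.raises(ValueError):
            make_cv_scheme(table, train_fraction=1.5)
        with pytest.raises(ValueError):
            make_cv_scheme(table, train_fraction=0.0)


class TestEvaluateModel:
    def test_noise_cv_at_chance(self):
        table = make_noise_table(seed=2)
        scheme = make_cv_scheme(table, n_repeats=40, seed=0)
        result = evaluate_model(table, [f"p{j}" for j in range(9)], scheme,
                                n_trees=100, seed=0)
        lo, hi = chance_band_99(14, 70)
        assert lo <= result.mean <= hi

    def test_separable_cv_high(self):
        table = make_separable_table(seed=3)
        scheme = make_cv_scheme(table, n_repeats=20, seed=0)
        result = evaluate_model(table, [f"p{j}" for j in range(9)], scheme,
                                n_trees=100, seed=0)
        assert result.mean > 95.0

    def test_deterministic_rerun(self):
        table = make_noise_table(seed=4)
        scheme = make_cv_scheme(table, n_repeats=8, seed=0)
        r1 = evaluate_model(table, ["p0", "p1"], scheme, n_trees=30, seed=5)
        r2 = evaluate_model(table, ["p0", "p1"], scheme, n_trees=30, seed=5)
        assert np.array_equal(r1.cv_accuracies, r2.cv_accuracies)

    def test_accuracies_bounded(self):
        table = make_noise_table(seed=5)
        scheme = make_cv_scheme(table, n_repeats=10, seed=0)
        result = evaluate_model(table, ["p0"], scheme, n_trees=20, seed=0)
        assert np.all((result.cv_accuracies >= 0) & (result.cv_accuracies <= 100))
        assert len(result.cv_accuracies) == 10

    def test_duplicated_column_leaves_expected_accuracy_unchanged(self):
        table = make_separable_table(seed=6, within_sd=2.0)
        table["p0_dup"] = table["p0"]
        scheme = make_cv_scheme(table, n_repeats=30, seed=0)
        cols = [f"p{j}" for j in range(9)]
        base = evaluate_model(table, cols, scheme, n_trees=100, seed=0)
        dup = evaluate_model(table, cols + ["p0_dup"], scheme, n_trees=100, seed=1)
        assert abs(base.mean - dup.mean) < 6.0

    def test_oob_and_cv_agree_on_separable_cohort(self):
        table = make_separable_table(n_per_line=8, seed=7)
        scheme = make_cv_scheme(table, n_repeats=20, seed=0)
        result = evaluate_model(table, [f"p{j}" for j in range(9)], scheme,
                                n_trees=200, seed=0, compute_oob=True)
        assert abs(result.oob_accuracy - result.mean) < 10.0

    def test_label_permutation_calibration(self):
        table = make_separable_table(seed=8)
        rng = np.random.default_rng(0)
        table["line"] = rng.permutation(table["line"].to_numpy())
        scheme = make_cv_scheme(table, n_repeats=40, seed=0)
        result = evaluate_model(table, [f"p{j}" for j in range(9)], scheme,
                                n_trees=100, seed=0)
        lo, hi = chance_band_99(14, 70)
        assert lo <= result.mean <= hi


class TestCompareModels:
    def test_self_comparison_zero_and_degenerate(self):
        table = make_noise_table(seed=9)
        scheme = make_cv_scheme(table, n_repeats=10, seed=0)
        result = evaluate_model(table, ["p0", "p1"], scheme, n_trees=30, seed=0)
        cmp = compare_models(result, result)
        assert cmp.mean_difference == 0.0
        assert cmp.degenerate

    def test_constant_shift(self):
        table = make_noise_table(seed=10)
        scheme = make_cv_scheme(table, n_repeats=25, seed=0)
        a = evaluate_model(table, ["p0", "p1"], scheme, n_trees=30, seed=0,
                           model_name="a")
        shifted = np.clip(a.cv_accuracies + 5.0, 0, 100)
        from tumorline.classify import ModelResult

        b = ModelResult("b", a.columns, shifted,
                        scheme_fingerprint=a.scheme_fingerprint)
        cmp = compare_models(a, b)
        assert cmp.mean_difference == pytest.approx(5.0)
        assert cmp.p_value < 1e-20 or cmp.degenerate

    def test_ci_contains_mean(self):
        table = make_noise_table(seed=11)
        scheme = make_cv_scheme(table, n_repeats=30, seed=0)
        a = evaluate_model(table, ["p0"], scheme, n_trees=30, seed=0)
        b = evaluate_model(table, ["p1"], scheme, n_trees=30, seed=1)
        cmp = compare_models(a, b)
        assert cmp.ci95[0] <= cmp.mean_difference <= cmp.ci95[1]

    def test_mismatched_schemes_refused(self):
        table = make_noise_table(seed=12)
        s1 = make_cv_scheme(table, n_repeats=10, seed=0)
        s2 = make_cv_scheme(table, n_repeats=10, seed=1)
        a = evaluate_model(table, ["p0"], s1, n_trees=10, seed=0)
        b = evaluate_model(table, ["p0"], s2, n_trees=10, seed=0)
        with pytest.raises(ValueError, match="scheme"):
            compare_models(a, b)

    def test_paired_design_reduces_difference_se(self):
        table = make_separable_table(seed=13, within_sd=3.0)
        scheme = make_cv_scheme(table, n_repeats=60, seed=0)
        cols = [f"p{j}" for j in range(9)]
        a = evaluate_model(table, cols[:5], scheme, n_trees=60, seed=0)
        b = evaluate_model(table, cols, scheme, n_trees=60, seed=1)
        n = len(a.cv_accuracies)
        paired_se = np.std(b.cv_accuracies - a.cv_accuracies, ddof=1) / np.sqrt(n)
        unpaired_se = np.sqrt(np.var(a.cv_accuracies, ddof=1) / n
                              + np.var(b.cv_accuracies, ddof=1) / n)
        assert paired_se < unpaired_se


class TestParameterImportance:
    def test_constant_column_zero_importance(self):
        table = make_separable_table(seed=14)
        table["const"] = 1.0
        imp = parameter_importance(table, ["p0", "p1", "const"], n_trees=200, seed=0)
        assert imp["const"] == pytest.approx(0.0, abs=1e-12)

    def test_single_informative_column_largest(self):
        table = make_noise_table(seed=15)
        line_idx = pd.factorize(table["line"])[0]
        rng = np.random.default_rng(0)
        table["signal"] = line_idx * 3.0 + rng.normal(0, 0.3, len(table))
        cols = [f"p{j}" for j in range(5)] + ["signal"]
        imp = parameter_importance(table, cols, n_trees=300, seed=0)
        assert imp.idxmax() == "signal"
        assert imp["signal"] > 3 * imp.drop("signal").abs().max()

    def test_reproducible_under_fixed_seed(self):
        table = make_separable_table(seed=16)
        cols = ["p0", "p1", "p2"]
        i1 = parameter_importance(table, cols, n_trees=100, seed=2)
        i2 = parameter_importance(table, cols, n_trees=100, seed=2)
        pd.testing.assert_series_equal(i1, i2)


class TestSubsetSweep:
    def test_model_counts_match_binomial(self):
        from math import comb

        table = make_noise_table(seed=17)
        table = table.rename(columns={f"p{j}": name
                                      for j, name in enumerate(IHC_PARAMETERS)})
        scheme = make_cv_scheme(table, n_repeats=2, seed=0)
        per_model, per_k, _ = subset_sweep(table, k_range=(1, 2, 6), scheme=scheme,
                                           n_trees=5, seed=0)
        counts = per_k.set_index("k")["n_models"]
        assert counts[1] == 9
        assert counts[2] == comb(9, 2) == 36
        assert counts[6] == comb(9, 6) == 84

    def test_k_out_of_range_rejected(self):
        table = make_noise_table(seed=0)
        table = table.rename(columns={f"p{j}": name
                                      for j, name in enumerate(IHC_PARAMETERS)})
        with pytest.raises(ValueError, match="outside"):
            subset_sweep(table, k_range=(9,), n_trees=5, n_repeats=2)
        with pytest.raises(ValueError, match="outside"):
            subset_sweep(table, k_range=(0,), n_trees=5, n_repeats=2)

    def test_consecutive_k_tests_emitted(self):
        table = make_separable_table(seed=18)
        table = table.rename(columns={f"p{j}": name
                                      for j, name in enumerate(IHC_PARAMETERS)})
        scheme = make_cv_scheme(table, n_repeats=3, seed=0)
        _, per_k, tests = subset_sweep(table, k_range=(1, 2, 3), scheme=scheme,
                                       n_trees=10, seed=0)
        assert tests[["k_prev", "k_next"]].values.tolist() == [[1, 2], [2, 3]]
        assert tests["p_value"].notna().all()
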