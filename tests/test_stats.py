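import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from splicebins.stats import (
    bh_adjust,
    compare_psi_groups,
    correlate_psi_expression,
    ihc_scores,
    permutation_correlation_test,
    trim_outliers,
)


class TestTrimOutliers:
    def test_single_extreme_value_removed(self):
        values = [0.0] * 19 + [100.0]
        kept, removed = trim_outliers(values, k_sd=2)
        # z of the 100 is (100-5)/22.3607 = 4.2485
        assert list(removed) == [19]
        assert len(kept) == 19

    def test_constant_vector_untouched(self):
        kept, removed = trim_outliers([0.5] * 10)
        assert len(kept) == 10 and len(removed) == 0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            trim_outliers([])

    def test_removal_set_is_exactly_the_z_exceeders(self, rng):
        for _ in range(50):
            v = rng.normal(0, 1, size=30)
            kept, removed = trim_outliers(v, k_sd=2)
            z = np.abs(v - v.mean()) / v.std(ddof=1)
            np.testing.assert_array_equal(removed, np.flatnonzero(z > 2))

    def test_no_removal_when_all_within(self):
        v = np.array([1.0, 2.0, 3.0, 2.0, 1.5])
        _, removed = trim_outliers(v, k_sd=3)
        assert len(removed) == 0


class TestComparePsiGroups:
    def _series(self, a, b):
        psi = pd.Series(
            list(a) + list(b), index=[f"s{i}" for i in range(len(a) + len(b))]
        )
        design = pd.Series(
            ["g1"] * len(a) + ["g2"] * len(b), index=psi.index
        )
        return psi, design

    def test_equal_constant_groups(self):
        psi, design = self._series([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        res = compare_psi_groups(psi, design)
        assert res.effect == 0.0
        assert res.statistic == 0.0

    def test_hand_computed_t(self):
        # {0.2,0.3,0.25} vs {0.6,0.7,0.65}: t = 9.7980, p = 6.0818e-4
        psi, design = self._series([0.2, 0.3, 0.25], [0.6, 0.7, 0.65])
        res = compare_psi_groups(psi, design)
        assert res.statistic == pytest.approx(9.797958971, abs=1e-8)
        assert res.p_value == pytest.approx(6.081849445e-4, rel=1e-8)
        assert res.effect == pytest.approx(0.4)

    def test_agreement_with_direct_formula(self, rng):
        a = rng.normal(0.4, 0.1, size=12)
        b = rng.normal(0.6, 0.15, size=9)
        psi, design = self._series(a, b)
        res = compare_psi_groups(psi, design)
        ref = sps.ttest_ind(b, a, equal_var=False)
        assert res.statistic == pytest.approx(float(ref.statistic), abs=1e-10)
        assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-10)

    def test_three_group_anova_with_tukey(self, rng):
        psi = pd.Series(rng.normal(0.5, 0.1, size=30), index=[f"s{i}" for i in range(30)])
        design = pd.Series(["a"] * 10 + ["b"] * 10 + ["c"] * 10, index=psi.index)
        res = compare_psi_groups(psi, design)
        assert res.method == "anova_tukey"
        assert res.pairwise is not None and len(res.pairwise) == 3
        ref = sps.f_oneway(psi[:10], psi[10:20], psi[20:])
        assert res.statistic == pytest.approx(float(ref.statistic), abs=1e-10)

    def test_null_anova_rarely_rejects(self):
        rng = np.random.default_rng(1)  # fixed: stochastic calibration check
        rejections = 0
        for _ in range(100):
            psi = pd.Series(rng.normal(0.5, 0.1, size=30), index=[f"s{i}" for i in range(30)])
            design = pd.Series(["a"] * 10 + ["b"] * 10 + ["c"] * 10, index=psi.index)
            res = compare_psi_groups(psi, design, compute_pairwise=False)
            if res.p_value < 0.05:
                rejections += 1
        assert rejections <= 6  # >=94% non-rejection under the null

    def test_trimming_drops_outlier(self):
        psi, design = self._series([0.2, 0.21, 0.19, 0.2], [0.6, 0.61, 0.59, 5.0])
        res = compare_psi_groups(psi, design, trim=True)
        assert sum(res.n_used.values()) == 7

    def test_group_emptied_by_missing_errors(self):
        psi = pd.Series([0.1, 0.2, np.nan, np.nan], index=["a", "b", "c", "d"])
        design = pd.Series(["g1", "g1", "g2", "g2"], index=psi.index)
        with pytest.raises(ValueError):
            compare_psi_groups(psi, design)


class TestCorrelation:
    def test_perfect_linear(self):
        psi = np.array([0.1, 0.2, 0.3, 0.4])
        res = correlate_psi_expression(psi, 2 * psi + 1)
        assert res.effect == pytest.approx(1.0)

    def test_perfect_negative(self):
        psi = np.array([0.1, 0.2, 0.3, 0.4])
        assert correlate_psi_expression(psi, -psi).effect == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        psi = [0.1, 0.4, 0.2, 0.8, 0.6]
        expr = [1, 2, 1.5, 3, 2.5]
        res = correlate_psi_expression(psi, expr)
        assert res.effect == pytest.approx(0.9938837346736189, abs=1e-12)

    def test_spearman_monotone(self):
        psi = [0.1, 0.2, 0.3, 0.9]
        expr = [1.0, 10.0, 100.0, 1000.0]
        assert correlate_psi_expression(psi, expr, method="spearman").effect == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        res = correlate_psi_expression([0.5, 0.5, 0.5], [1, 2, 3])
        assert "zero_variance" in res.flags
        assert np.isnan(res.effect)

    def test_missing_dropped(self):
        res = correlate_psi_expression([0.1, np.nan, 0.3, 0.4], [1, 2, 3, 4])
        assert res.n_used["pairs"] == 3

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError):
            correlate_psi_expression([0.1, np.nan], [1, 2])


def _null_dataset(rng, n_exons=60, n_samples=30):
    mat = pd.DataFrame(
        rng.uniform(0.05, 0.95, size=(n_exons, n_samples)),
        index=[f"b{i}" for i in range(n_exons)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    expr = rng.normal(5, 1, size=n_samples)
    return mat, expr


class TestPermutationTest:
    def test_observed_above_all_nulls_gives_zero_p(self, rng):
        mat, expr = _null_dataset(rng)
        # make one target row perfectly correlated with expression
        mat.loc["b0"] = (expr - expr.min()) / (expr.max() - expr.min() + 1e-9)
        res = permutation_correlation_test(
            mat, expr, ["b0"], [f"b{i}" for i in range(1, 60)], n_perm=200, seed=1
        )
        assert res.empirical_p == 0.0

    def test_background_equal_to_targets_gives_p_one(self, rng):
        mat, expr = _null_dataset(rng, n_exons=10)
        ids = list(mat.index)
        res = permutation_correlation_test(
            mat, expr, ids, ids, n_perm=100, seed=1, strict_greater=False
        )
        assert res.empirical_p == 1.0

    def test_determinism(self, rng):
        mat, expr = _null_dataset(rng)
        kw = dict(
            target_ids=[f"b{i}" for i in range(5)],
            background_ids=[f"b{i}" for i in range(5, 60)],
            n_perm=300,
        )
        r1 = permutation_correlation_test(mat, expr, seed=42, **kw)
        r2 = permutation_correlation_test(mat, expr, seed=42, **kw)
        assert r1.empirical_p == r2.empirical_p
        assert r1.null_mean == r2.null_mean

    def test_empty_target_set_errors(self, rng):
        mat, expr = _null_dataset(rng)
        with pytest.raises(ValueError):
            permutation_correlation_test(mat, expr, [], list(mat.index), n_perm=10)

    def test_small_background_errors(self, rng):
        mat, expr = _null_dataset(rng)
        with pytest.raises(ValueError):
            permutation_correlation_test(mat, expr, list(mat.index)[:10], ["b0"], n_perm=10)

    def test_constant_target_row_counts_as_zero(self, rng):
        mat, expr = _null_dataset(rng)
        mat.loc["b0"] = 0.5
        res = permutation_correlation_test(
            mat, expr, ["b0"], [f"b{i}" for i in range(1, 60)], n_perm=50, seed=0
        )
        assert res.observed_mean_abs_r == 0.0

    def test_plus_one_correction(self, rng):
        mat, expr = _null_dataset(rng)
        mat.loc["b0"] = (expr - expr.min()) / (expr.max() - expr.min() + 1e-9)
        res = permutation_correlation_test(
            mat, expr, ["b0"], [f"b{i}" for i in range(1, 60)],
            n_perm=100, seed=0, plus_one_correction=True,
        )
        assert res.empirical_p == pytest.approx(1 / 101)

    def test_power_with_planted_coupling(self, rng):
        """Targets coupled to expression at rho = 0.5 are detected."""
        hits = 0
        for rep in range(10):
            n = 50
            expr = rng.normal(0, 1, size=n)
            rows = {}
            for i in range(30):
                noise = rng.normal(0, 1, size=n)
                rows[f"t{i}"] = 0.5 + 0.1 * (0.5 * expr + np.sqrt(1 - 0.25) * noise)
            for i in range(200):
                rows[f"b{i}"] = rng.uniform(0.1, 0.9, size=n)
            mat = pd.DataFrame(rows).T
            res = permutation_correlation_test(
                mat, expr, [f"t{i}" for i in range(30)],
                [f"b{i}" for i in range(200)], n_perm=500, seed=rep,
            )
            if res.empirical_p <= 0.05:
                hits += 1
        assert hits >= 9


class TestIhcScores:
    def test_all_negative(self):
        s = ihc_scores((100, 0, 0, 0))
        assert s.percent_positive == 0 and s.h_score == 0

    def test_all_high(self):
        s = ihc_scores((0, 0, 0, 100))
        assert s.percent_positive == 100 and s.h_score == 300

    def test_uniform_quarters(self):
        s = ihc_scores((25, 25, 25, 25))
        assert s.percent_positive == pytest.approx(75)
        assert s.h_score == pytest.approx(150)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            ihc_scores((-1, 0, 0, 10))

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            ihc_scores((0, 0, 0, 0))


def test_bh_adjust_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    p = rng.uniform(size=40)
    np.testing.assert_allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])


def test_bh_adjust_propagates_nan():
    q = bh_adjust([0.01, np.nan, 0.5])
    assert np.isnan(q[1]) and not np.isnan(q[0])
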