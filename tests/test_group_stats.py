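import numpy as np
import pytest
from scipy import stats as sps

from pelthg.group_stats import (
    StatsError,
    layer_correlation,
    layer_summary,
    paired_layer_test,
    region_anova,
    tukey_hsd,
    variance_ratio_test,
)


class TestPairedLayerTest:
    def test_hand_computed_t(self):
        # differences [1,1,1,3]: mean 1.5, sd 1, n 4 -> t = 3.0, df = 3
        uc = np.array([0.0, 0.0, 0.0, 0.0])
        tc = uc + np.array([1.0, 1.0, 1.0, 3.0])
        res = paired_layer_test(tc, uc)
        assert res.statistic == pytest.approx(3.0)
        assert res.df == 3
        assert res.estimate == pytest.approx(1.5)

    def test_sign_flip_negates_t_keeps_p(self, rng):
        tc = rng.normal(size=20)
        uc = rng.normal(size=20)
        r1 = paired_layer_test(tc, uc)
        r2 = paired_layer_test(uc, tc)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_identical_layers_degenerate(self, rng):
        v = rng.normal(size=10)
        with pytest.raises(StatsError, match="variance"):
            paired_layer_test(v, v)

    def test_ci_covers_estimate(self, rng):
        tc, uc = rng.normal(size=15), rng.normal(size=15)
        r = paired_layer_test(tc, uc)
        assert r.ci_low < r.estimate < r.ci_high


class TestVarianceRatio:
    def test_identical_samples(self, rng):
        v = rng.normal(size=12)
        r = variance_ratio_test(v, v)
        assert r.statistic == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)

    def test_quarter_ratio(self):
        a = np.array([0.0, 1.0, 2.0])   # var 1
        b = np.array([0.0, 2.0, 4.0])   # var 4
        r = variance_ratio_test(a, b)
        assert r.statistic == pytest.approx(0.25)
        assert r.df == (2, 2)

    def test_reciprocity(self, rng):
        a, b = rng.normal(size=10), 2 * rng.normal(size=14)
        r1 = variance_ratio_test(a, b)
        r2 = variance_ratio_test(b, a)
        assert r1.statistic == pytest.approx(1 / r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)


class TestLayerCorrelation:
    def test_exact_linear_gives_r_one(self, rng):
        tc = rng.uniform(1, 3, size=12)
        r = layer_correlation(tc, 2 * tc)
        assert r.estimate == pytest.approx(1.0)

    def test_hand_zero_correlation(self):
        tc = np.array([0.0, 1.0, 2.0])
        uc = np.array([0.0, 1.0, 0.0])
        r = layer_correlation(tc, uc)
        assert r.estimate == pytest.approx(0.0, abs=1e-12)

    def test_affine_invariance(self, rng):
        tc, uc = rng.normal(size=25), rng.normal(size=25)
        r1 = layer_correlation(tc, uc)
        r2 = layer_correlation(3 * tc + 1, 0.5 * uc - 2)
        assert r1.estimate == pytest.approx(r2.estimate)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_fisher_ci_brackets_r(self, rng):
        tc = rng.normal(size=30)
        uc = tc + rng.normal(size=30)
        r = layer_correlation(tc, uc)
        assert r.ci_low < r.estimate < r.ci_high

    def test_constant_input_rejected(self):
        with pytest.raises(StatsError):
            layer_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRegionAnova:
    def test_hand_computed_f(self):
        # groups [1,2,3], [2,3,4]: SSB = 1.5, MSW = 1 -> F = 1.5, df (1, 4)
        vals = [1.0, 2.0, 3.0, 2.0, 3.0, 4.0]
        labels = ["a"] * 3 + ["b"] * 3
        r = region_anova((vals, labels), "anatomical_region")
        assert r.statistic == pytest.approx(1.5)
        assert r.df == (1, 4)

    def test_label_permutation_invariance(self, rng):
        vals = rng.normal(size=30)
        labels = np.array(["a", "b", "c"] * 10)
        r1 = region_anova((vals, labels), "f")
        perm = rng.permutation(30)
        r2 = region_anova((vals[perm], labels[perm]), "f")
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_small_level_named_in_error(self):
        with pytest.raises(StatsError, match="tinylevel"):
            region_anova(([1.0, 2.0, 3.0], ["a", "a", "tinylevel"]), "f")

    def test_on_pelt_grid(self, grids):
        r = region_anova(grids[0], "anatomical_region")
        k = len({p.anatomical_region for p in grids[0].points})
        assert r.df == (k - 1, len(grids[0]) - k)
        assert 0 <= r.p_value <= 1


class TestTukey:
    def test_identical_groups(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        labels = ["a"] * 3 + ["b"] * 3
        t = tukey_hsd((vals, labels), "f")
        assert len(t) == 1
        assert t.rows[0].difference == pytest.approx(0.0)
        assert t.rows[0].p_adj == pytest.approx(1.0)

    def test_two_levels_equals_students_t(self, rng):
        a, b = rng.normal(size=10), rng.normal(loc=0.5, size=12)
        t = tukey_hsd((np.concatenate([a, b]),
                       ["a"] * 10 + ["b"] * 12), "f")
        p_t = sps.ttest_ind(a, b, equal_var=True).pvalue
        assert t.rows[0].p_adj == pytest.approx(p_t, abs=1e-9)

    def test_row_count_all_pairs(self, grids):
        t = tukey_hsd(grids[0], "anatomical_region")
        k = len({p.anatomical_region for p in grids[0].points})
        assert len(t) == k * (k - 1) // 2

    def test_adjusted_p_not_below_pairwise_t(self, grids):
        # on the same contrast (pooled MSE, pooled df) the Tukey-adjusted p
        # can never fall below the unadjusted t-test p
        g = grids[0]
        t = tukey_hsd(g, "anatomical_region")
        vals = g.thg
        labels = np.array([p.anatomical_region for p in g.points])
        groups = {lev: vals[labels == lev] for lev in set(labels.tolist())}
        n = len(vals)
        k = len(groups)
        mse = sum(np.sum((v - v.mean()) ** 2) for v in groups.values()) / (n - k)
        for row in t.rows:
            a, b = groups[row.level_a], groups[row.level_b]
            se = np.sqrt(mse * (1 / len(a) + 1 / len(b)))
            t_stat = (a.mean() - b.mean()) / se
            p_raw = 2 * sps.t.sf(abs(t_stat), n - k)
            assert row.p_adj >= p_raw - 1e-12

    def test_ci_half_width_positive(self, grids):
        t = tukey_hsd(grids[1], "fur_region")
        assert all(r.ci_half_width > 0 for r in t.rows)


class TestTypeIError:
    """Null calibration at alpha = 0.05 over repeated i.i.d. Gaussian draws."""

    def test_paired_t_calibrated(self):
        rng = np.random.default_rng(101)
        rej = sum(
            paired_layer_test(rng.normal(size=30),
                              rng.normal(size=30)).p_value < 0.05
            for _ in range(1000))
        assert 0.03 <= rej / 1000 <= 0.07

    def test_variance_ratio_calibrated(self):
        rng = np.random.default_rng(102)
        rej = sum(
            variance_ratio_test(rng.normal(size=25),
                                rng.normal(size=25)).p_value < 0.05
            for _ in range(1000))
        assert 0.03 <= rej / 1000 <= 0.07

    def test_anova_calibrated(self):
        rng = np.random.default_rng(103)
        labels = ["a"] * 15 + ["b"] * 15 + ["c"] * 15
        rej = sum(
            region_anova((rng.normal(size=45), labels), "f").p_value < 0.05
            for _ in range(1000))
        assert 0.03 <= rej / 1000 <= 0.07


def test_layer_summary_fields(grids):
    s = layer_summary(grids[0])
    assert s["n"] == len(grids[0])
    assert s["min"] <= s["mean"] <= s["max"]
    assert "mehg_n" in s  # topcoat carries an assayed subset
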