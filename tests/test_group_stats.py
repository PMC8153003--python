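import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stressmirseg as s
from stressmirseg.group_stats import StatsError, significance_stars, tukey_hsd


def dagostino_k2_reference(x):
    """Independent hand-coded D'Agostino-Pearson omnibus statistic, from
    the published skewness (D'Agostino 1970) and kurtosis
    (Anscombe & Glynn 1983) z-transforms."""
    x = np.asarray(x, float)
    n = x.size
    m = x.mean()
    m2 = ((x - m) ** 2).mean()
    m3 = ((x - m) ** 3).mean()
    m4 = ((x - m) ** 4).mean()
    g1 = m3 / m2 ** 1.5
    b2 = m4 / m2 ** 2
    # skewness z
    y = g1 * np.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = (3.0 * (n ** 2 + 27 * n - 70) * (n + 1) * (n + 3)
             / ((n - 2) * (n + 5) * (n + 7) * (n + 9)))
    w2 = -1.0 + np.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / np.sqrt(0.5 * np.log(w2))
    alpha = np.sqrt(2.0 / (w2 - 1.0))
    z1 = delta * np.log(y / alpha + np.sqrt((y / alpha) ** 2 + 1.0))
    # kurtosis z
    eb2 = 3.0 * (n - 1) / (n + 1)
    vb2 = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    xk = (b2 - eb2) / np.sqrt(vb2)
    sqrtb1 = (6.0 * (n ** 2 - 5 * n + 2) / ((n + 7) * (n + 9))
              * np.sqrt(6.0 * (n + 3) * (n + 5) / (n * (n - 2) * (n - 3))))
    a = 6.0 + 8.0 / sqrtb1 * (2.0 / sqrtb1 + np.sqrt(1.0 + 4.0 / sqrtb1 ** 2))
    z2 = ((1.0 - 2.0 / (9.0 * a))
          - ((1.0 - 2.0 / a) / (1.0 + xk * np.sqrt(2.0 / (a - 4.0)))) ** (1 / 3)
          ) / np.sqrt(2.0 / (9.0 * a))
    return z1 ** 2 + z2 ** 2


class TestDagostinoPearson:
    FIXED = np.array([1.2, 3.4, 0.7, 2.2, 5.1, 4.4, 3.3, 2.8, 1.9, 0.4,
                      6.0, 2.1, 3.9, 2.5, 1.1, 4.8, 3.0, 2.9, 0.9, 5.5])

    def test_matches_reference_formulas(self):
        k2, p = s.dagostino_pearson(self.FIXED)
        expected = dagostino_k2_reference(self.FIXED)
        assert k2 == pytest.approx(expected, abs=1e-6)
        assert p == pytest.approx(float(stats.chi2.sf(expected, 2)), abs=1e-9)
        assert k2 >= 0.0

    def test_small_n_is_explicit_error(self):
        with pytest.raises(StatsError, match="n >= 8"):
            s.dagostino_pearson(np.arange(7))

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(42)
        ps = [s.dagostino_pearson(rng.normal(size=200))[1]
              for _ in range(300)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestAnova:
    def test_identical_groups_null_case(self):
        g = [1.0, 2.0, 3.0]
        res = s.one_way_anova([g, g, g])
        assert (res.F, res.p) == (0.0, 1.0)

    def test_hand_sum_of_squares(self):
        # groups {1,2,3},{2,3,4},{3,4,5}: SSB=6 (df 2), SSW=6 (df 6) -> F=3
        res = s.one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.F == pytest.approx(3.0, abs=1e-12)
        assert res.p == pytest.approx(float(stats.f.sf(3.0, 2, 6)), abs=1e-12)

    def test_zero_within_variance_distinct_means(self):
        res = s.one_way_anova([[1.0, 1.0], [2.0, 2.0]])
        assert np.isinf(res.F) and res.p == 0.0

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=12), rng.normal(1.0, 1.0, size=9)
        res = s.one_way_anova([a, b])
        t = stats.ttest_ind(a, b)
        assert res.F == pytest.approx(t.statistic ** 2, abs=1e-9)
        assert res.p == pytest.approx(t.pvalue, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError, match="size"):
            s.one_way_anova([[1.0, 2.0], []])


class TestTukey:
    BALANCED = [[1.0, 2.0, 3.0, 4.0, 5.0],
                [2.0, 3.0, 4.0, 5.0, 6.0],
                [4.0, 5.0, 6.0, 7.0, 8.0]]

    def test_hand_computed_q(self):
        # each group var 2.5 -> MSW 2.5, se = sqrt(2.5/2 * 2/5) = sqrt(0.5)
        comps = {c.pair: c for c in tukey_hsd(self.BALANCED, "abc")}
        se = np.sqrt(0.5)
        assert comps[("a", "b")].q == pytest.approx(1.0 / se, abs=1e-9)
        assert comps[("a", "c")].q == pytest.approx(3.0 / se, abs=1e-9)
        assert comps[("b", "c")].q == pytest.approx(2.0 / se, abs=1e-9)

    def test_critical_value_matches_published_table(self):
        # studentized-range upper 5% point for k=3, df=12 is 3.77 (standard
        # published tables)
        q05 = stats.studentized_range.ppf(0.95, 3, 12)
        assert q05 == pytest.approx(3.77, abs=0.01)
        # a pair sitting exactly at the critical q gets adjusted p = 0.05
        se = np.sqrt(0.5)
        comps = {c.pair: c for c in tukey_hsd(self.BALANCED, "abc")}
        pair = comps[("b", "c")]
        assert pair.p_adjusted == pytest.approx(
            float(stats.studentized_range.sf(pair.q, 3, 12)), abs=1e-12)

    def test_matches_scipy_tukey_hsd(self):
        """Cross-check the in-package Tukey-Kramer against scipy's
        implementation on unbalanced groups."""
        rng = np.random.default_rng(3)
        groups = [rng.normal(size=n) for n in (12, 7, 11)]
        ours = {c.pair: c.p_adjusted
                for c in tukey_hsd(groups, ("0", "1", "2"))}
        ref = stats.tukey_hsd(*groups)
        for i in range(3):
            for j in range(i + 1, 3):
                assert ours[(str(i), str(j))] == pytest.approx(
                    ref.pvalue[i, j], abs=1e-6)

    def test_null_pair_and_conservativeness(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(size=8) for _ in range(3)]
        groups[1] = groups[0] + 0.0
        comps = tukey_hsd(groups, "abc")
        by_pair = {c.pair: c for c in comps}
        assert by_pair[("a", "b")].q == pytest.approx(0.0)
        assert by_pair[("a", "b")].p_adjusted == pytest.approx(1.0)
        # adjusted p never below the pooled two-sample p for the same pair
        n_total = sum(len(g) for g in groups)
        df = n_total - 3
        msw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum()
                  for g in groups) / df
        for c in comps:
            i, j = "abc".index(c.pair[0]), "abc".index(c.pair[1])
            t = abs(np.mean(groups[i]) - np.mean(groups[j])) / np.sqrt(
                msw * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            p_two_sample = 2.0 * stats.t.sf(t, df)
            assert c.p_adjusted >= p_two_sample - 1e-12

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(StatsError, match="variance"):
            tukey_hsd([[1.0, 1.0], [2.0, 2.0]])


class TestPearson:
    def test_identity(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert s.pearson(x, x).r == pytest.approx(1.0)

    def test_hand_product_moment(self):
        res = s.pearson([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.r == pytest.approx(0.6)  # cov 3 / sqrt(5*5)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r = s.pearson(x, y).r
        assert s.pearson(y, x).r == pytest.approx(r)
        assert s.pearson(3.0 * x + 7.0, y).r == pytest.approx(r)
        assert s.pearson(-2.0 * x, y).r == pytest.approx(-r)

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError, match="variance"):
            s.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @pytest.mark.parametrize("r,n,printed", [
        (-0.40, 30, 0.03),   # hippocampal miRNA:FKBP5 entries
        (-0.43, 30, 0.02),
        (0.66, 16, 0.005),   # hypothalamic miRNA:BDNF
    ])
    def test_p_value_rounds_to_published_precision(self, r, n, printed):
        decimals = len(str(printed).split(".")[1])
        assert round(s.pearson_pvalue(r, n), decimals) == printed


class TestCorrelationMatrix:
    def test_entries_match_pairwise_pearson(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("wxyz"))
        mat = s.correlation_matrix(data)
        for a in "wxyz":
            assert mat.r.loc[a, a] == 1.0
            for b in "wxyz":
                if a != b:
                    ref = s.pearson(data[a], data[b])
                    assert mat.r.loc[a, b] == pytest.approx(ref.r)
                    assert mat.p.loc[a, b] == pytest.approx(ref.p)

    def test_missing_variable_marked_not_computable(self):
        rng = np.random.default_rng(6)
        data = pd.DataFrame(rng.normal(size=(10, 2)), columns=["x", "y"])
        data["z"] = np.nan
        mat = s.correlation_matrix(data, ["x", "y", "z"])
        assert mat.formatted.loc["z", "x"] == "NC"
        assert np.isnan(mat.r.loc["x", "z"])
        assert mat.formatted.loc["y", "x"].startswith(
            f"{mat.r.loc['x', 'y']:.2f}")

    def test_star_codes(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.06) == ""
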