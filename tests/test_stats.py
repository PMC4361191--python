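"""Statistical kernel: F tails, balanced 2x2 ANOVA, Pearson r, %EPT."""

import math

import numpy as np
import pytest
import scipy.stats
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from streamdiag.errors import DataError
from streamdiag.stats import anova2, f_sf, pct_ept, pearson_r


class TestFSurvival:
    @pytest.mark.parametrize(
        "F,df1,df2,printed,decimals",
        [
            (8.2, 1, 60, 0.006, 3),
            (9.87, 1, 60, 0.003, 3),
            (17.5, 1, 6, 0.006, 3),
            (14.1, 1, 6, 0.01, 2),
        ],
    )
    def test_matches_printed_p_values(self, F, df1, df2, printed, decimals):
        """p-values recomputed from printed F statistics round to the printed p."""
        assert round(f_sf(F, df1, df2), decimals) == printed

    def test_nutrient_regression_p_within_rounding_slack(self):
        """F(1,26)=2.06 converts to p = 0.164 within the slack of the rounded F.

        The exact tail of F=2.06 is 0.1631; 0.164 corresponds to F=2.048,
        inside the rounding interval of the printed statistic.
        """
        assert abs(f_sf(2.06, 1, 26) - 0.164) < 1e-3

    def test_sediment_regression_below_alpha(self):
        assert f_sf(5.42, 1, 26) < 0.03

    def test_whole_mass_above_zero(self):
        assert f_sf(0.0, 1, 60) == 1.0

    @pytest.mark.parametrize("df1,df2", [(1, 1), (1, 60), (3, 10), (10, 3), (2, 200)])
    def test_ten_digit_agreement_with_independent_oracle(self, df1, df2):
        for F in (0.01, 0.3, 1.0, 2.5, 8.0, 40.0, 300.0):
            mine = f_sf(F, df1, df2)
            ref = scipy.stats.f.sf(F, df1, df2)
            assert mine == pytest.approx(ref, rel=1e-10)

    @given(st.floats(0.01, 200.0), st.floats(0.02, 210.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing_in_F(self, f_lo, f_hi):
        lo, hi = sorted((f_lo, f_hi))
        assert f_sf(hi, 1, 26) <= f_sf(lo, 1, 26)

    @pytest.mark.parametrize("F,df", [(2.3, 7), (0.4, 30), (11.0, 3)])
    def test_equals_two_sided_t_tail_for_df1_one(self, F, df):
        t_tail = 2 * scipy.stats.t.sf(math.sqrt(F), df)
        assert f_sf(F, 1, df) == pytest.approx(t_tail, rel=1e-10)

    def test_rejects_negative_F_and_bad_df(self):
        with pytest.raises(DataError):
            f_sf(-1.0, 1, 10)
        with pytest.raises(DataError):
            f_sf(1.0, 0, 10)


class TestAnova2:
    @staticmethod
    def _design(n_cell, rng=None, means=None):
        a = np.repeat([1, 1, 2, 2], n_cell)
        b = np.tile(np.repeat([1, 2], n_cell), 2)
        if means is None:
            means = {key: 0.0 for key in [(1, 1), (1, 2), (2, 1), (2, 2)]}
        y = np.array([means[(i, j)] for i, j in zip(a, b)], dtype=float)
        if rng is not None:
            y = y + rng.normal(0, 1, len(y))
        return y, a, b

    def test_all_equal_values_give_zero_ss_and_F(self):
        y, a, b = self._design(4)
        t = anova2(y + 7.0, a, b)
        assert t.factor_a.ss == t.factor_b.ss == t.interaction.ss == 0.0
        assert t.factor_a.F == 0.0

    def test_pure_main_effect_with_zero_noise_flags_infinite_F(self):
        means = {(1, 1): 10, (1, 2): 10, (2, 1): 20, (2, 2): 20}
        y, a, b = self._design(2, means=means)
        t = anova2(y, a, b)
        assert t.zero_residual
        assert math.isinf(t.factor_a.F) and t.factor_a.p == 0.0
        assert t.factor_b.ss == 0.0 and t.interaction.ss == 0.0

    def test_matches_design_matrix_oracle_to_ten_digits(self):
        """Full agreement with an OLS indicator-contrast decomposition."""
        rng = np.random.default_rng(42)
        means = {(1, 1): 5, (1, 2): 6, (2, 1): 5.5, (2, 2): 9}
        y, a, b = self._design(16, rng=rng, means=means)
        t = anova2(y, a, b)
        # independent route: sequential SS from nested OLS fits (balanced
        # design, so order does not matter)
        ca = np.where(a == 2, 1.0, -1.0)
        cb = np.where(b == 2, 1.0, -1.0)
        X_full = np.column_stack([np.ones_like(y), ca, cb, ca * cb])

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return float(np.sum((y - X @ beta) ** 2))

        rss0 = rss(X_full[:, :1])
        rss_a = rss(X_full[:, :2])
        rss_ab = rss(X_full[:, :3])
        rss_full = rss(X_full)
        assert t.factor_a.ss == pytest.approx(rss0 - rss_a, rel=1e-10)
        assert t.factor_b.ss == pytest.approx(rss_a - rss_ab, rel=1e-10)
        assert t.interaction.ss == pytest.approx(rss_ab - rss_full, rel=1e-10)
        assert t.residual.ss == pytest.approx(rss_full, rel=1e-10)
        # and the p-values against statsmodels' F machinery
        df_res = len(y) - 4
        for term, ss in [(t.factor_a, rss0 - rss_a), (t.factor_b, rss_a - rss_ab)]:
            F_ref = (ss / 1) / (rss_full / df_res)
            assert term.F == pytest.approx(F_ref, rel=1e-10)
            assert term.p == pytest.approx(scipy.stats.f.sf(F_ref, 1, df_res), rel=1e-10)

    def test_ss_conservation(self):
        rng = np.random.default_rng(7)
        y, a, b = self._design(16, rng=rng)
        t = anova2(y, a, b)
        total = t.factor_a.ss + t.factor_b.ss + t.interaction.ss + t.residual.ss
        assert total == pytest.approx(t.ss_total, rel=1e-10)

    def test_unbalanced_design_is_rejected(self):
        y, a, b = self._design(4)
        with pytest.raises(DataError):
            anova2(y[:-1], a[:-1], b[:-1])

    def test_statsmodels_cross_check(self, mesocosm_table):
        """Same F as statsmodels OLS anova on a generated response."""
        import statsmodels.formula.api as smf

        df = mesocosm_table.rename(
            columns={"nutrient_level": "nut", "sediment_level": "sed"}
        )[["chlorophyll_a", "nut", "sed"]].copy()
        t = anova2(df["chlorophyll_a"], df["nut"], df["sed"])
        fit = smf.ols("chlorophyll_a ~ C(nut) * C(sed)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        assert t.factor_a.F == pytest.approx(table.loc["C(nut)", "F"], rel=1e-8)
        assert t.factor_b.F == pytest.approx(table.loc["C(sed)", "F"], rel=1e-8)


class TestPearson:
    def test_identity_and_reflection(self):
        x = np.arange(10.0)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        # long-hand covariance formula
        ref = float(
            np.sum((x - x.mean()) * (y - y.mean()))
            / math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert pearson_r(x, y) == pytest.approx(ref, rel=1e-12)
        assert pearson_r(x, y) == pytest.approx(scipy.stats.pearsonr(x, y).statistic, rel=1e-12)

    def test_zero_variance_defined_as_zero(self):
        assert pearson_r([1, 1, 1, 1], [0, 2, 4, 6]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            pearson_r([1, 2, 3], [1, 2])


class TestPctEpt:
    @pytest.mark.parametrize("ept,total,expected", [(0, 100, 0.0), (100, 100, 100.0), (1, 4, 25.0)])
    def test_exact_fractions(self, ept, total, expected):
        assert pct_ept(ept, total) == expected

    def test_undefined_for_zero_total(self):
        with pytest.raises(DataError):
            pct_ept(0, 0)

    @given(st.integers(0, 500), st.integers(1, 500))
    @settings(max_examples=50, deadline=None)
    def test_bounded(self, ept, extra):
        total = ept + extra
        assert 0.0 <= pct_ept(ept, total) <= 100.0
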