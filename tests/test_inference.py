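"""Robust regression, coefficient comparison, Sobel mediation, JZS Bayes
factors and the power utility."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hyperdisc import CohortConfig, ValidationError, generate_cohort
from hyperdisc.encoding import standardize
from hyperdisc.inference import (
    RegressionResult,
    bayes_factor_nested,
    compare_betas,
    jzs_log_bf10,
    mediation_analysis,
    power_sample_size,
    robust_fit,
    sobel_test,
    spearman,
)


def _X(**cols):
    return pd.DataFrame(cols)


class TestRobustFit:
    def test_noiseless_line_recovered_exactly(self):
        x = np.linspace(-3, 3, 40)
        res = robust_fit(_X(x=x), 2.0 * x, standardize_inputs=False)
        assert res.coef("x") == pytest.approx(2.0, abs=1e-8)
        assert res.coef("intercept") == pytest.approx(0.0, abs=1e-8)

    def test_matches_ols_on_clean_gaussian_data(self):
        """On outlier-free Gaussian data the bisquare estimate agrees with OLS
        to within a fraction of a standard error (the bisquare has ~95%
        Gaussian efficiency, so the two estimators nearly coincide)."""
        rng = np.random.default_rng(11)
        n = 500
        x = rng.normal(size=n)
        y = 1.0 + 0.5 * x + rng.normal(size=n)
        res = robust_fit(_X(x=x), y, standardize_inputs=False)
        X1 = np.column_stack([np.ones(n), x])
        ols = np.linalg.lstsq(X1, y, rcond=None)[0]
        se = 1.0 / math.sqrt(n)
        assert res.coef("x") == pytest.approx(ols[1], abs=se)
        assert res.coef("intercept") == pytest.approx(ols[0], abs=se)

    def test_resists_gross_outliers_better_than_ols(self):
        """10% wild outliers on y: the robust slope beats OLS nearly always."""
        rng = np.random.default_rng(5)
        n, wins, n_sims = 200, 0, 200
        for _ in range(n_sims):
            x = rng.normal(size=n)
            y = x + 0.5 * rng.normal(size=n)
            idx = rng.choice(n, size=n // 10, replace=False)
            y[idx] += 50.0
            rob = robust_fit(_X(x=x), y, standardize_inputs=False).coef("x")
            ols = np.linalg.lstsq(np.column_stack([np.ones(n), x]), y, rcond=None)[0][1]
            wins += abs(rob - 1.0) < abs(ols - 1.0)
        assert wins >= 0.95 * n_sims

    def test_standardized_single_predictor_matches_pearson(self):
        rng = np.random.default_rng(8)
        n = 1000
        x = rng.normal(size=n)
        y = 0.3 * x + rng.normal(size=n)
        res = robust_fit(_X(x=x), y)
        r = np.corrcoef(x, y)[0, 1]
        assert res.coef("x") == pytest.approx(r, abs=0.02)

    def test_df_and_pvalue_convention(self):
        rng = np.random.default_rng(1)
        n = 50
        X = _X(a=rng.normal(size=n), b=rng.normal(size=n))
        y = rng.normal(size=n)
        res = robust_fit(X, y)
        assert res.df_resid == n - 3
        i = list(res.names).index("a")
        expected_p = 2 * stats.t.sf(abs(res.tvalues[i]), n - 3)
        assert res.pvalues[i] == pytest.approx(expected_p)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            robust_fit(_X(x=np.ones(20)), np.arange(20.0))

    def test_rank_deficiency_rejected(self):
        x = np.arange(20.0)
        with pytest.raises(ValidationError):
            robust_fit(_X(a=x, b=2 * x), np.random.default_rng(0).normal(size=20))

    def test_summary_renders(self):
        rng = np.random.default_rng(2)
        res = robust_fit(_X(x=rng.normal(size=30)), rng.normal(size=30))
        assert "df = 28" in res.summary()


class TestCompareBetas:
    def _result(self, b, var, cov_ab=0.0, df=100):
        cov = np.array([[1e-4, 0, 0], [0, var[0], cov_ab], [0, cov_ab, var[1]]])
        bse = np.sqrt(np.diag(cov))
        t = np.array([0.0, *(np.array(b) / bse[1:])])
        return RegressionResult(
            names=("intercept", "a", "b"), params=np.array([0.0, *b]), bse=bse,
            tvalues=t, pvalues=2 * stats.t.sf(np.abs(t), df), df_resid=df,
            nobs=df + 3, r_squared=0.1, cov=cov, standardized=True,
        )

    def test_self_comparison_is_null(self):
        res = self._result([0.5, 0.3], [0.01, 0.01])
        t, p = compare_betas(res, "a", "a")
        assert t == 0.0 and p == 1.0

    def test_hand_computed_value(self):
        res = self._result([0.5, 0.3], [0.01, 0.01], cov_ab=0.0)
        t, p = compare_betas(res, "a", "b")
        assert t == pytest.approx(0.2 / math.sqrt(0.02), rel=1e-9)  # ~1.41421

    def test_antisymmetric(self):
        res = self._result([0.5, 0.3], [0.01, 0.02], cov_ab=0.005)
        t_ab, p_ab = compare_betas(res, "a", "b")
        t_ba, p_ba = compare_betas(res, "b", "a")
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_unknown_name_rejected(self):
        res = self._result([0.5, 0.3], [0.01, 0.01])
        with pytest.raises(KeyError):
            compare_betas(res, "a", "nope")


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman(x, -np.exp(x))[0] == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, 60).astype(float)  # heavy ties
        y = x + rng.integers(0, 3, 60)
        rho, _ = spearman(x, y)
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValidationError):
            spearman(np.ones(10), np.arange(10.0))


class TestSobel:
    def test_zero_path_gives_zero_statistic(self):
        res = sobel_test(0.0, 0.1, 0.4, 0.2)
        assert res.statistic == 0.0

    def test_hand_computed_value(self):
        res = sobel_test(0.5, 0.1, 0.4, 0.2)
        assert res.statistic == pytest.approx(0.2 / math.sqrt(0.0016 + 0.01), rel=1e-9)
        assert res.statistic == pytest.approx(1.85695, abs=1e-4)
        assert res.p_normal == pytest.approx(2 * stats.norm.sf(res.statistic))

    def test_symmetric_in_paths(self):
        a = sobel_test(0.5, 0.1, 0.4, 0.2)
        b = sobel_test(0.4, 0.2, 0.5, 0.1)
        assert a.statistic == pytest.approx(b.statistic)

    def test_double_null_degenerate(self):
        res = sobel_test(0.0, 0.1, 0.0, 0.2)
        assert res.statistic == 0.0 and res.p_normal == 1.0

    @settings(max_examples=100, derandomize=True)
    @given(
        a=st.floats(-2, 2), b=st.floats(-2, 2),
        se_a=st.floats(0.01, 1), se_b=st.floats(0.01, 1),
    )
    def test_matches_literal_formula(self, a, b, se_a, se_b):
        res = sobel_test(a, se_a, b, se_b)
        denom = math.sqrt(b * b * se_a**2 + a * a * se_b**2)
        expected = 0.0 if denom == 0 else a * b / denom
        assert res.statistic == pytest.approx(expected, rel=1e-12, abs=1e-12)


class TestMediation:
    @staticmethod
    def _encoded(n, seed, full_mediation=False):
        rng = np.random.default_rng(seed)
        shock = (rng.random(n) < 0.5).astype(float)
        if full_mediation:
            affect = 0.5 * standardize(shock) + rng.normal(size=n)
            log_k = 0.4 * standardize(affect) + rng.normal(size=n)
        else:
            affect = rng.normal(size=n)
            log_k = 0.12 * standardize(shock) + 0.08 * standardize(affect) + rng.normal(size=n)
        return pd.DataFrame(
            {"shock01": shock, "affect_score": affect, "log_k": log_k,
             "age": rng.normal(44, 15, n), "gender": (rng.random(n) < 0.5).astype(int),
             "education": rng.integers(1, 6, n), "income": rng.lognormal(10.8, 0.7, n)}
        )

    def test_independent_causes_give_null_sobel(self):
        med = mediation_analysis(self._encoded(1145, 0), controls=True)
        assert med.sobel.p_normal > 0.05

    def test_full_mediation_detected(self):
        med = mediation_analysis(self._encoded(1145, 1, full_mediation=True), controls=True)
        assert med.sobel.p_normal < 0.05
        assert med.product > 0

    def test_controls_toggle_changes_models(self):
        df = self._encoded(300, 2)
        with_ = mediation_analysis(df, controls=True)
        without = mediation_analysis(df, controls=False)
        assert with_.beta_model.df_resid == 300 - 7
        assert without.beta_model.df_resid == 300 - 3

    def test_missing_column_rejected(self):
        with pytest.raises(ValidationError, match="affect_score"):
            mediation_analysis(pd.DataFrame({"shock01": [0, 1], "log_k": [0.1, 0.2]}))


def _trapezoid_log_bf10(n, p, r2, nodes=10_000, lo=-15.0, hi=35.0):
    """Independent oracle: brute-force log-space trapezoid of the JZS integral."""
    t = np.linspace(lo, hi, nodes)
    g = np.exp(t)
    log_pi = 0.5 * np.log(n / 2.0) - 0.5 * np.log(np.pi) - 1.5 * t - n / (2.0 * g)
    logf = ((n - 1 - p) / 2.0) * np.log1p(g) - ((n - 1) / 2.0) * np.log1p(g * (1 - r2)) + log_pi + t
    m = logf.max()
    return m + np.log(np.trapezoid(np.exp(logf - m), t))


class TestBayesFactor:
    @pytest.mark.parametrize("n", [50, 184, 1145])
    @pytest.mark.parametrize("r2", [0.0, 0.05, 0.2])
    def test_quadrature_matches_trapezoid_oracle(self, n, r2):
        log_bf, method = jzs_log_bf10(n, 5, r2)
        assert method == "quadrature"
        oracle = _trapezoid_log_bf10(n, 5, r2)
        assert abs(math.exp(log_bf - oracle) - 1) < 0.01  # BF agreement within 1%

    def test_equal_r2_penalises_extra_predictor(self):
        res = bayes_factor_nested(0.10, 6, 0.10, 5, n=184)
        assert 0 < res.bf < 1

    def test_monotone_in_full_r2(self):
        bfs = [bayes_factor_nested(r2, 6, 0.08, 5, n=184).bf for r2 in (0.08, 0.12, 0.2, 0.3)]
        assert all(a < b for a, b in zip(bfs, bfs[1:]))

    def test_laplace_close_to_quadrature(self):
        lq, _ = jzs_log_bf10(1145, 6, 0.067, method="quadrature")
        ll, _ = jzs_log_bf10(1145, 6, 0.067, method="laplace")
        assert lq == pytest.approx(ll, abs=0.05)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            jzs_log_bf10(100, 5, 1.0)
        with pytest.raises(ValidationError):
            bayes_factor_nested(0.1, 5, 0.1, 5, n=100)


class TestPower:
    def test_headline_sample_size(self):
        assert power_sample_size(0.2, 0.05, 0.80) == 194

    def test_matches_fisher_z_oracle(self):
        for eff, alpha, power in [(0.2, 0.05, 0.8), (0.5, 0.05, 0.8), (0.1, 0.01, 0.9)]:
            za, zb = stats.norm.ppf(1 - alpha / 2), stats.norm.ppf(power)
            oracle = math.ceil((za + zb) ** 2 / math.atanh(eff) ** 2 + 3)
            assert power_sample_size(eff, alpha, power) == oracle

    def test_monotone_in_power_and_effect(self):
        assert power_sample_size(0.2, 0.05, 0.9) > power_sample_size(0.2, 0.05, 0.8)
        assert power_sample_size(0.1, 0.05, 0.8) > power_sample_size(0.2, 0.05, 0.8)

    def test_exact_t_near_fisher_z(self):
        n_f = power_sample_size(0.2, 0.05, 0.8)
        n_t = power_sample_size(0.2, 0.05, 0.8, method="exact_t")
        assert abs(n_f - n_t) <= 5

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValidationError):
            power_sample_size(0.0)
        with pytest.raises(ValidationError):
            power_sample_size(0.2, alpha=1.5)
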