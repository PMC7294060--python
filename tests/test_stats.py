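import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fcgraph.stats import (
    StatsError,
    fit_longitudinal_trend,
    icc_oneway,
    mediation_bootstrap,
    standardized_regression,
    variability_regression,
    visit_variability,
    yeo_johnson,
)
from fcgraph.synth import CohortConfig, generate_covariates, generate_mediation_data


class TestYeoJohnson:
    def test_lambda_one_is_identity(self, rng):
        x = rng.normal(2, 3, 100)
        out, spec = yeo_johnson(x, lmbda=1.0)
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_lambda_zero_log_branch(self):
        out, _ = yeo_johnson(np.array([np.e - 1.0]), lmbda=0.0)
        assert out[0] == pytest.approx(1.0)

    def test_negative_branch_lambda_two(self):
        out, _ = yeo_johnson(np.array([-(np.e - 1.0)]), lmbda=2.0)
        assert out[0] == pytest.approx(-1.0)

    def test_ml_lambda_reduces_skewness(self, rng):
        x = rng.standard_normal(500) ** 2
        out, spec = yeo_johnson(x)
        assert abs(sps.skew(out)) < abs(sps.skew(x))
        assert spec.lmbda != 1.0

    def test_matches_scipy_mle(self, rng):
        """Own bounded-search MLE agrees with scipy's unconstrained one."""
        for x in (rng.standard_normal(80) ** 2, rng.normal(5, 2, 60), -np.abs(rng.normal(0, 3, 70))):
            ours, spec = yeo_johnson(x)
            theirs, lam = sps.yeojohnson(x)
            assert spec.lmbda == pytest.approx(lam, abs=1e-4)
            np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_nonfinite_rejected(self):
        with pytest.raises(StatsError):
            yeo_johnson(np.array([1.0, np.nan]))


class TestStandardizedRegression:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        res = standardized_regression(2 * x, x)
        assert res.std_beta == pytest.approx(1.0)
        assert res.p_bonferroni == pytest.approx(min(1, 10 * res.p_raw))

    def test_independent_large_sample_beta_near_zero(self, rng):
        res = standardized_regression(rng.normal(size=10_000), rng.normal(size=10_000))
        assert abs(res.std_beta) < 0.05

    def test_power_at_reported_effect_size(self, rng):
        """A std beta of -.39 at n=41 rejects (uncorrected) in most replicates."""
        hits = 0
        for _ in range(300):
            x = rng.standard_normal(41)
            y = -0.39 * x + np.sqrt(1 - 0.39**2) * rng.standard_normal(41)
            res = standardized_regression(y, x)
            hits += res.p_raw < 0.05
        assert hits / 300 > 0.5

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        x, y = rng.normal(size=50), rng.normal(size=50)
        res = standardized_regression(y, x)
        xz = (x - x.mean()) / x.std(ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        fit = sm.OLS(yz, sm.add_constant(xz)).fit()
        assert res.std_beta == pytest.approx(fit.params[1], abs=1e-10)
        assert res.p_raw == pytest.approx(fit.pvalues[1], abs=1e-10)
        assert res.adj_r2 == pytest.approx(fit.rsquared_adj, abs=1e-10)

    def test_zero_variance_errors(self):
        with pytest.raises(StatsError):
            standardized_regression(np.ones(10), np.arange(10.0))


class TestMediation:
    def test_perfect_chain(self):
        x = np.linspace(-1, 1, 20)
        res = mediation_bootstrap(x, x.copy(), x.copy(), n_boot=0)
        assert res.indirect == pytest.approx(1.0)
        assert res.total == pytest.approx(1.0)
        assert res.direct == pytest.approx(0.0, abs=1e-10)

    def test_decomposition_identity(self, rng):
        x, m, y = (rng.normal(size=60) for _ in range(3))
        res = mediation_bootstrap(x, m, y, n_boot=0)
        assert res.indirect + res.direct == pytest.approx(res.total, abs=1e-6)

    def test_point_estimates_match_statsmodels(self, rng):
        import statsmodels.api as sm

        x, m, y = generate_mediation_data(0.5, 0.4, 0.2, 200, rng)
        res = mediation_bootstrap(x, m, y, n_boot=0)
        xz = (x - x.mean()) / x.std(ddof=1)
        mz = (m - m.mean()) / m.std(ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        a = sm.OLS(mz, sm.add_constant(xz)).fit().params[1]
        fit = sm.OLS(yz, sm.add_constant(np.column_stack([mz, xz]))).fit()
        assert res.path_a == pytest.approx(a, abs=1e-8)
        assert res.path_b == pytest.approx(fit.params[1], abs=1e-8)
        assert res.direct == pytest.approx(fit.params[2], abs=1e-8)

    def test_bootstrap_reproducible(self, rng):
        x, m, y = generate_mediation_data(0.5, 0.4, 0.2, 41, rng)
        r1 = mediation_bootstrap(x, m, y, n_boot=500, seed=42)
        r2 = mediation_bootstrap(x, m, y, n_boot=500, seed=42)
        assert r1.p_boot == r2.p_boot
        assert r1.ci == r2.ci

    def test_consistency_at_large_n(self):
        rng = np.random.default_rng(99)
        x, m, y = generate_mediation_data(0.5, 0.4, 0.2, 2000, rng)
        res = mediation_bootstrap(x, m, y, n_boot=0)
        assert res.indirect == pytest.approx(0.20, abs=0.03)

    def test_too_few_cases_rejected(self, rng):
        with pytest.raises(StatsError):
            mediation_bootstrap(np.arange(5.0), np.arange(5.0), np.arange(5.0))


class TestICC:
    def test_perfect_repeatability(self):
        df = pd.DataFrame(
            {"subject_id": np.repeat(list("abcd"), 3), "value": np.repeat([1.0, 2, 3, 4], 3)}
        )
        res = icc_oneway(df)
        assert res.icc == pytest.approx(1.0)

    def test_null_data_icc_near_zero(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {"subject_id": np.repeat(range(200), 8), "value": rng.standard_normal(1600)}
        )
        res = icc_oneway(df)
        assert abs(res.icc) < 0.05

    def test_equal_variance_components_give_half(self):
        rng = np.random.default_rng(11)
        subj = np.repeat(rng.standard_normal(200), 8)
        df = pd.DataFrame(
            {"subject_id": np.repeat(range(200), 8), "value": subj + rng.standard_normal(1600)}
        )
        res = icc_oneway(df)
        assert res.icc == pytest.approx(0.5, abs=0.05)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_matches_pingouin_on_balanced_design(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        n, k = 25, 4
        df = pd.DataFrame(
            {
                "subject_id": np.repeat(range(n), k),
                "visit": np.tile(range(k), n),
                "value": np.repeat(rng.standard_normal(n), k) + 0.8 * rng.standard_normal(n * k),
            }
        )
        ours = icc_oneway(df)
        theirs = pg.intraclass_corr(
            data=df, targets="subject_id", raters="visit", ratings="value"
        ).set_index("Type").loc["ICC(1,1)"]
        assert ours.icc == pytest.approx(theirs["ICC"], abs=1e-6)
        ci = theirs["CI95"]  # pingouin rounds the interval to 2 decimals
        assert ours.ci_low == pytest.approx(ci[0], abs=6e-3)
        assert ours.ci_high == pytest.approx(ci[1], abs=6e-3)

    def test_single_visit_subject_excluded_with_warning(self):
        df = pd.DataFrame(
            {"subject_id": ["a", "a", "b", "b", "c"], "value": [1.0, 1.1, 2.0, 2.1, 9.0]}
        )
        with pytest.warns(RuntimeWarning, match="single visit"):
            res = icc_oneway(df)
        assert res.n_subjects == 2


class TestLongitudinalTrend:
    def test_noiseless_slope_recovered(self):
        rows = []
        for i in range(10):
            for v in range(5):
                rows.append({"subject_id": i, "time": 30.0 * v, "value": 0.001 * 30.0 * v})
        fit = fit_longitudinal_trend(pd.DataFrame(rows))
        assert fit.beta_time == pytest.approx(0.001, abs=1e-8)

    def test_planted_slope_with_subject_effects(self):
        """The fixed slope is recovered within 2 SE in most replicates."""
        rng = np.random.default_rng(21)
        covered, methods = 0, set()
        for rep in range(15):
            rows = []
            for i in range(44):
                u0, u1 = rng.normal(0, 1.0), rng.normal(0, 0.002)
                for v in range(8):
                    t = 30.0 * v
                    rows.append(
                        {
                            "subject_id": i,
                            "time": t,
                            "value": 0.005 * t + u0 + u1 * t + 0.3 * rng.standard_normal(),
                        }
                    )
            fit = fit_longitudinal_trend(pd.DataFrame(rows))
            covered += abs(fit.beta_time - 0.005) <= 2 * fit.se_time
            methods.add(fit.method)
        assert covered >= 12
        assert all("wald-t" in m for m in methods)


class TestVariability:
    def test_constant_metric_gives_zero_sd(self):
        df = pd.DataFrame({"subject_id": ["a"] * 4, "value": [2.0] * 4})
        out = visit_variability(df)
        assert out["sd"].iloc[0] == 0.0
        assert out["cv"].iloc[0] == 0.0

    def test_simple_sd_and_cv(self):
        df = pd.DataFrame({"subject_id": ["a"] * 3, "value": [1.0, 2.0, 3.0]})
        out = visit_variability(df)
        assert out["sd"].iloc[0] == pytest.approx(1.0)
        assert out["cv"].iloc[0] == pytest.approx(0.5)

    def test_sampling_distribution_of_sd(self):
        """Mean sample SD over many subjects matches sigma*c4 for n=8 visits."""
        rng = np.random.default_rng(13)
        sigma, k = 0.7, 8
        df = pd.DataFrame(
            {
                "subject_id": np.repeat(range(1000), k),
                "value": sigma * rng.standard_normal(8000),
            }
        )
        out = visit_variability(df)
        from scipy.special import gamma

        c4 = np.sqrt(2 / (k - 1)) * gamma(k / 2) / gamma((k - 1) / 2)
        assert out["sd"].mean() == pytest.approx(sigma * c4, rel=0.05)

    def test_few_visit_subjects_excluded(self):
        df = pd.DataFrame(
            {"subject_id": ["a", "a", "a", "b", "b"], "value": [1.0, 2, 3, 4, 5]}
        )
        with pytest.warns(RuntimeWarning, match="excluding"):
            out = visit_variability(df)
        assert out["subject_id"].tolist() == ["a"]


class TestVariabilityRegression:
    @staticmethod
    def _records(covariates, sd_values):
        return pd.DataFrame(
            {"subject_id": covariates["subject_id"], "sd": sd_values, "mean": 1.0, "cv": sd_values}
        )

    def test_planted_age_effect_detected(self):
        rng = np.random.default_rng(17)
        config = CohortConfig(n_subjects=120, seed=17)
        cov = generate_covariates(config, rng)
        age_z = sps.zscore(cov["age"], ddof=1)
        sd = np.exp(0.8 * age_z + 0.3 * rng.standard_normal(120))
        res = variability_regression(self._records(cov, sd), cov)
        assert res["age"].std_beta > 0
        assert res["age"].p_bonferroni < 0.05

    def test_null_covariates_not_flagged(self):
        rng = np.random.default_rng(29)
        config = CohortConfig(n_subjects=60, seed=29)
        cov = generate_covariates(config, rng)
        sd = np.exp(rng.standard_normal(60))
        res = variability_regression(self._records(cov, sd), cov)
        # with Bonferroni n=10 per covariate, a null run should rarely flag
        flagged = [k for k, v in res.items() if v.p_bonferroni < 0.05]
        assert len(flagged) <= 1

    def test_constant_sd_errors(self):
        rng = np.random.default_rng(31)
        config = CohortConfig(n_subjects=30, seed=31)
        cov = generate_covariates(config, rng)
        with pytest.raises(StatsError, match="zero variance"):
            variability_regression(self._records(cov, np.ones(30)), cov)

    def test_collinear_covariates_detected(self):
        rng = np.random.default_rng(37)
        config = CohortConfig(n_subjects=40, seed=37)
        cov = generate_covariates(config, rng)
        cov = cov.assign(brain_volume=2.0 * cov["age"] + 5.0)
        sd = np.exp(rng.standard_normal(40))
        with pytest.raises(StatsError, match="collinear"):
            variability_regression(self._records(cov, sd), cov)
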