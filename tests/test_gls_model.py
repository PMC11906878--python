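import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from anthropause._countries import ECONOMIC_CLASSES
from anthropause.gls_model import (GLSModelSpec, HeteroscedasticGLS,
                                   NestingViolationError, RankDeficiencyError,
                                   anova_terms, build_design,
                                   conditional_effects, fit_gls,
                                   likelihood_ratio_test,
                                   residual_variance_test)
from anthropause.synthetic_data import (simulate_change_frame,
                                        simulate_gls_benchmark)


@pytest.fixture(scope="module")
def study_frame():
    return simulate_change_frame(np.random.default_rng(99))[0]


class TestEngine:
    def test_unit_multipliers_reproduce_ols_exactly(self, study_frame):
        fit = fit_gls(GLSModelSpec(estimation="ml"), study_frame,
                      fix_unit_multipliers=True)
        X, y, _, _ = build_design(study_frame)
        beta_ols = np.linalg.lstsq(X.to_numpy(), y, rcond=None)[0]
        assert np.allclose(fit.params["coef"].to_numpy(), beta_ols,
                           atol=1e-8)

    def test_loglik_is_monotone_over_iterations(self, rng):
        X, y, g, _ = simulate_gls_benchmark(rng, n_per_group=100)
        est = HeteroscedasticGLS(estimation="ml").fit(X.to_numpy(), y,
                                                      groups=g)
        assert np.all(np.diff(est.loglik_trace_) >= -1e-9)

    def test_multipliers_recovered_within_15_percent(self, rng):
        true = (1.0, 2.0, 4.0, 8.0)
        X, y, g, _ = simulate_gls_benchmark(rng, multipliers=true)
        est = HeteroscedasticGLS(estimation="ml").fit(X.to_numpy(), y,
                                                      groups=g)
        rel = np.abs(est.variance_multipliers_ - np.array(true)) / true
        assert np.all(rel < 0.15)

    def test_equal_variances_estimated_near_one(self, rng):
        X, y, g, _ = simulate_gls_benchmark(rng, multipliers=(1, 1, 1, 1))
        est = HeteroscedasticGLS(estimation="ml").fit(X.to_numpy(), y,
                                                      groups=g)
        assert np.all((est.variance_multipliers_ > 0.7) &
                      (est.variance_multipliers_ < 1.4))

    def test_prewhitened_data_reproduces_gls_coefficients(self, rng):
        """Dividing rows by their fitted multipliers and running plain OLS
        must give back the GLS solution (internal consistency)."""
        X, y, g, _ = simulate_gls_benchmark(rng, n_per_group=200)
        est = HeteroscedasticGLS(estimation="ml").fit(X.to_numpy(), y,
                                                      groups=g)
        d = est.variance_multipliers_[g]
        beta_w = np.linalg.lstsq(X.to_numpy() / d[:, None], y / d,
                                 rcond=None)[0]
        assert np.allclose(beta_w, est.coef_, atol=1e-8)

    def test_reference_multiplier_is_one_and_order_follows_classes(
            self, study_frame):
        fit = fit_gls(GLSModelSpec(estimation="ml"), study_frame)
        assert list(fit.variance_multipliers) == list(ECONOMIC_CLASSES)
        assert fit.variance_multipliers["developed"] == 1.0
        assert all(v > 0 for v in fit.variance_multipliers.values())

    def test_singular_design_names_aliased_column(self, study_frame):
        X, y, g, _ = build_design(study_frame)
        X = X.copy()
        X["dup"] = X["stringency_index"]
        est = HeteroscedasticGLS()
        est.feature_names_in_ = list(X.columns)
        with pytest.raises(RankDeficiencyError):
            est.fit(X.to_numpy(), y, groups=g)

    def test_tiny_variance_group_rejected(self, study_frame):
        frame = study_frame[study_frame["economic_class"] != "emerging"]
        frame = pd.concat([frame, study_frame[
            study_frame["economic_class"] == "emerging"].head(1)])
        with pytest.raises(ValueError, match="< 2 observations"):
            fit_gls(GLSModelSpec(estimation="ml"),
                    frame.reset_index(drop=True))

    def test_matches_reference_gls_implementation(self, tmp_path,
                                                  study_frame):
        """Independent oracle: nlme's gls with a per-class variance
        structure must agree on ML coefficients and log-likelihood."""
        fit = fit_gls(GLSModelSpec(estimation="ml"), study_frame)
        csv = tmp_path / "frame.csv"
        study_frame.to_csv(csv, index=False)
        script = tmp_path / "gls.R"
        script.write_text(textwrap.dedent(f"""
            library(nlme)
            d <- read.csv("{csv}")
            d$economic_class <- factor(d$economic_class,
                levels=c("developed","emerging","developing",
                         "least_developed"))
            m <- gls(log_change ~ stringency_index + change_park_visitors
                     + log10_population_size + economic_class, data=d,
                     weights=varIdent(form=~1|economic_class), method="ML")
            cat(logLik(m), coef(m), sep="\\n")
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        vals = [float(v) for v in out.stdout.split()]
        assert fit.loglik == pytest.approx(vals[0], abs=1e-4)
        assert np.allclose(fit.params["coef"].to_numpy(), vals[1:],
                           rtol=1e-5, atol=1e-8)


class TestLikelihoodRatio:
    def test_reported_interaction_comparison(self):
        """The base-vs-interaction comparison: log-likelihoods -41.11 and
        -37.49 on 3 df give statistic 7.24 and p just above 0.06."""
        stat, p = likelihood_ratio_test(-41.11, -37.49, df=3)
        assert stat == pytest.approx(7.24, abs=1e-9)
        assert p == pytest.approx(0.064, abs=1e-3)

    def test_identical_likelihoods_give_p_one(self):
        stat, p = likelihood_ratio_test(-10.0, -10.0, df=2)
        assert stat == 0.0 and p == 1.0

    def test_chi_square_quantile_identity(self):
        _, p = likelihood_ratio_test(0.0, 3.841 / 2.0, df=1)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_nesting_violation_detected(self):
        with pytest.raises(NestingViolationError):
            likelihood_ratio_test(-5.0, -9.0, df=1)

    def test_bad_df_rejected(self):
        with pytest.raises(ValueError):
            likelihood_ratio_test(-5.0, -4.0, df=0)


class TestAnova:
    def test_zero_interaction_p_values_are_uniform(self):
        """With no true interaction, the marginal interaction p-value is
        Uniform(0,1) across replicate worlds (KS check)."""
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(150):
            frame, _ = simulate_change_frame(rng)
            fit = fit_gls(GLSModelSpec(estimation="ml", interaction=True),
                          frame)
            tab = anova_terms(fit).set_index("term")
            pvals.append(tab.loc["stringency_index:economic_class", "p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_strong_interaction_detected(self):
        rng = np.random.default_rng(8)
        hits = 0
        reps = 40
        for _ in range(reps):
            X, y, g, _ = simulate_gls_benchmark(rng, n_per_group=150,
                                                multipliers=(1, 1.5, 2, 3))
            # inject a genuine slope difference for group 2 on x1
            y = y + 1.0 * X["x1"].to_numpy() * (g == 2)
            frame = pd.DataFrame({
                "log_change": y,
                "stringency_index": X["x1"],
                "change_park_visitors": X["x2"],
                "log10_population_size": rng.uniform(5, 8, len(y)),
                "economic_class": np.array(ECONOMIC_CLASSES)[g],
            })
            fit = fit_gls(GLSModelSpec(estimation="ml", interaction=True),
                          frame)
            tab = anova_terms(fit).set_index("term")
            hits += tab.loc["stringency_index:economic_class", "p"] < 0.05
        assert hits / reps >= 0.95

    def test_interaction_listed_last_and_dead_column_excluded(
            self, study_frame):
        frame = study_frame[study_frame["economic_class"] !=
                            "least_developed"].reset_index(drop=True)
        with pytest.warns(UserWarning, match="all-zero design column"):
            fit = fit_gls(GLSModelSpec(estimation="ml", interaction=True),
                          frame)
        tab = anova_terms(fit)
        assert tab["term"].iloc[-1] == "stringency_index:economic_class"


class TestConditionalEffects:
    def test_profile_at_covariate_means_matches_weighted_prediction(
            self, study_frame):
        fit = fit_gls(GLSModelSpec(estimation="ml"), study_frame)
        eff = conditional_effects(fit, "stringency_index", n_grid=3)
        # manually rebuild the mid-grid prediction
        beta = fit.params["coef"]
        frame = study_frame
        econ = frame["economic_class"].astype(str)
        pred = (beta["intercept"]
                + beta["stringency_index"] * eff["value"].iloc[1]
                + beta["change_park_visitors"]
                * frame["change_park_visitors"].mean()
                + beta["log10_population_size"]
                * frame["log10_population_size"].mean()
                + sum(beta[f"economic_class[{lv}]"] * (econ == lv).mean()
                      for lv in ECONOMIC_CLASSES[1:]))
        assert eff["predicted"].iloc[1] == pytest.approx(pred)
        assert (eff["lo"] < eff["predicted"]).all()
        assert (eff["predicted"] < eff["hi"]).all()

    def test_positive_slope_gives_monotone_profile(self, study_frame):
        fit = fit_gls(GLSModelSpec(estimation="ml"), study_frame)
        eff = conditional_effects(fit, "change_park_visitors")
        slope = fit.params.loc["change_park_visitors", "coef"]
        diffs = np.diff(eff["predicted"])
        assert np.all(diffs > 0) if slope > 0 else np.all(diffs < 0)

    def test_categorical_profile_has_one_row_per_class(self, study_frame):
        fit = fit_gls(GLSModelSpec(estimation="ml"), study_frame)
        eff = conditional_effects(fit, "economic_class")
        assert list(eff["value"]) == list(ECONOMIC_CLASSES)

    def test_unknown_focal_term_rejected(self, study_frame):
        fit = fit_gls(GLSModelSpec(estimation="ml"), study_frame)
        with pytest.raises(ValueError, match="not in the model"):
            conditional_effects(fit, "gdp")


class TestLevene:
    def test_equal_spread_groups_give_zero_statistic(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        resid = np.concatenate([a, a + 10.0])
        groups = np.repeat(["g1", "g2"], 4)
        stat, p = residual_variance_test(resid, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_sixteen_fold_variance_ratio_detected(self, rng):
        resid = np.concatenate([rng.normal(0, 1, 100),
                                rng.normal(0, 4, 100)])
        groups = np.repeat(["a", "b"], 100)
        _, p = residual_variance_test(resid, groups)
        assert p < 0.01

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(21)
        rejections = 0
        reps = 400
        for _ in range(reps):
            resid = rng.normal(0, 1, 200)
            groups = np.repeat(list("abcd"), 50)
            _, p = residual_variance_test(resid, groups)
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.025)

    def test_small_group_excluded_with_warning(self):
        resid = np.array([1.0, 2.0, 3.0, 4.0, 99.0])
        groups = np.array(["a", "a", "b", "b", "c"])
        with pytest.warns(UserWarning, match="excluded"):
            residual_variance_test(resid, groups)

    def test_mean_centred_variant_available(self, rng):
        resid = np.concatenate([rng.normal(0, 1, 50),
                                rng.normal(0, 2, 50)])
        groups = np.repeat(["a", "b"], 50)
        s_med, _ = residual_variance_test(resid, groups, center="median")
        s_mean, _ = residual_variance_test(resid, groups, center="mean")
        assert s_med != s_mean
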