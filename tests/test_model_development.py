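"""REML fitting, nested-deviance comparison, Wald tests, equation development."""

import numpy as np
import pandas as pd
import pytest

import herbenergy as he
from herbenergy.core import DomainError
from herbenergy.model_development import FitError, ModelSpec

SPEC_DE_DMD = ModelSpec(response="DE", fixed=("DMD",), random=())
SPEC_DE_DMD_FULL = ModelSpec(response="DE", fixed=("DMD",),
                             random=("sheep", "season", "year"))


def _ols(frame, ycol, xcols):
    X = np.column_stack([np.ones(len(frame))] + [frame[c] for c in xcols])
    beta, *_ = np.linalg.lstsq(X, frame[ycol], rcond=None)
    return beta


class TestModelSpec:
    def test_config_string_round_trip(self):
        spec = ModelSpec.from_config(
            "response: DE; fixed: [DMD, N, GE]; random: [sheep, season, year]")
        assert spec == ModelSpec(response="DE", fixed=("DMD", "N", "GE"),
                                 random=("sheep", "season", "year"))

    def test_response_cannot_be_a_predictor(self):
        with pytest.raises(DomainError):
            ModelSpec(response="DE", fixed=("DE",))

    def test_unknown_factor_rejected(self):
        with pytest.raises(DomainError):
            ModelSpec(response="DE", fixed=("DMD",), random=("paddock",))


class TestFitREML:
    def test_zero_group_variance_reduces_to_ols(self, default_data):
        # the exact zero-variance limit: noise orthogonal to every grouping
        # factor (centred within trial, hence within season and year too)
        rng = np.random.default_rng(7)
        frame = default_data.copy()
        noise = rng.normal(0, 0.4, len(frame))
        noise -= pd.Series(noise).groupby(frame["trial_id"].values) \
            .transform("mean").values
        frame["de"] = 2.0 + 15.0 * frame["dmd"] + noise
        fit = he.fit_reml(frame, SPEC_DE_DMD_FULL)
        assert all(v == 0 for v in fit.variance_components.values())
        beta = _ols(frame, "de", ["dmd"])
        est = [fit.coefficients["Intercept"], fit.coefficients["DMD"]]
        np.testing.assert_allclose(est, beta, rtol=1e-6)

    def test_no_random_factors_is_exactly_ols_with_classical_ses(self, default_data):
        fit = he.fit_reml(default_data, SPEC_DE_DMD)
        X = np.column_stack([np.ones(len(default_data)), default_data["dmd"]])
        y = default_data["de"].to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        sigma2 = resid @ resid / (len(y) - 2)
        ses = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        np.testing.assert_allclose(list(fit.coefficients.values()), beta, rtol=1e-10)
        np.testing.assert_allclose(list(fit.std_errors.values()), ses, rtol=1e-10)

    def test_collinear_response_handled_without_crash(self, default_data):
        frame = default_data.copy()
        frame["de"] = 1.0 + 2.0 * frame["dmd"]  # exact linear function
        fit = he.fit_reml(frame, SPEC_DE_DMD)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.residual_variance > 0  # floored, not zero or negative

    def test_rank_deficient_design_names_collinear_terms(self, default_data):
        spec = ModelSpec(response="ME", fixed=("N", "CP"), random=())
        with pytest.raises(FitError, match="collinear"):
            he.fit_reml(default_data, spec)

    def test_estimates_invariant_to_record_and_predictor_order(self, default_data):
        spec = ModelSpec(response="ME", fixed=("DMD", "N", "GE"),
                         random=("season", "year"))
        fit = he.fit_reml(default_data, spec)
        shuffled = default_data.sample(frac=1.0, random_state=3)
        fit_shuffled = he.fit_reml(shuffled, spec)
        reordered = he.fit_reml(
            default_data, ModelSpec(response="ME", fixed=("GE", "N", "DMD"),
                                    random=("season", "year")))
        assert fit.deviance == pytest.approx(fit_shuffled.deviance, abs=1e-7)
        for term in ("Intercept", "DMD", "N", "GE"):
            # agreement to optimiser tolerance: the profiled surface is flat
            # near the optimum, so permutations shift gamma in its 5th decimal
            assert fit.coefficients[term] == pytest.approx(
                fit_shuffled.coefficients[term], rel=1e-4, abs=1e-6)
            assert fit.coefficients[term] == pytest.approx(
                reordered.coefficients[term], rel=1e-4, abs=1e-6)

    def test_variance_components_are_nonnegative(self, default_data):
        fit = he.fit_reml(default_data, SPEC_DE_DMD_FULL)
        assert all(v >= 0 for v in fit.variance_components.values())
        assert fit.residual_variance > 0
        assert 0 <= fit.r2 <= 1

    def test_agrees_with_independent_mixed_model_implementation(self):
        """Cross-check variance components and coefficients against
        statsmodels' MixedLM on data with a real trial-level effect."""
        import statsmodels.formula.api as smf

        cfg = he.GeneratorConfig(seed=31)
        cfg.random_effect_var = {"trial": 0.6}
        eq = {e.id: e for e in he.load_builtin_registry("table2")}["1a"]
        frame = he.generate_from_equation(eq, cfg, noise_sd=0.5)
        fit = he.fit_reml(frame, ModelSpec(response="DE", fixed=("DMD",),
                                           random=("trial",)))
        sm_fit = smf.mixedlm("de ~ dmd", frame, groups=frame["trial_id"]) \
            .fit(reml=True, method="lbfgs")
        assert fit.coefficients["DMD"] == pytest.approx(
            sm_fit.params["dmd"], rel=1e-3)
        assert fit.coefficients["Intercept"] == pytest.approx(
            sm_fit.params["Intercept"], rel=1e-3, abs=1e-3)
        assert fit.variance_components["trial"] == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), rel=0.02)
        assert fit.residual_variance == pytest.approx(sm_fit.scale, rel=0.02)

    def test_parameter_recovery_under_trial_structure(self):
        """Refitting a known univariate form on simulated trials recovers the
        true coefficients within 3 SEs in nearly all replicates."""
        eq = {e.id: e for e in he.load_builtin_registry("table2")}["1a"]
        hits = 0
        n_rep = 60
        for i in range(n_rep):
            frame = he.generate_from_equation(eq, he.GeneratorConfig(seed=800 + i),
                                              noise_sd=0.947)
            fit = he.fit_reml(frame, SPEC_DE_DMD_FULL)
            ok = (abs(fit.coefficients["DMD"] - 18.552)
                  <= 3 * fit.std_errors["DMD"])
            ok &= (abs(fit.coefficients["Intercept"] - (-0.527))
                   <= 3 * fit.std_errors["Intercept"])
            hits += ok
        assert hits / n_rep >= 0.95


class TestCompareRandomStructures:
    def test_identical_models_give_zero_statistic(self, default_data):
        fit = he.fit_reml(default_data, ModelSpec(response="DE", fixed=("DMD",),
                                                  random=("season",)))
        stat, df, p = he.compare_random_structures(fit, fit)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_full_deviance_never_exceeds_nested(self, default_data):
        full = he.fit_reml(default_data, SPEC_DE_DMD_FULL)
        for reduced_random in ((), ("season",), ("sheep", "year"),
                               ("season", "year")):
            reduced = he.fit_reml(default_data,
                                  ModelSpec(response="DE", fixed=("DMD",),
                                            random=reduced_random))
            assert full.deviance <= reduced.deviance + 1e-6

    def test_mismatched_fixed_models_rejected(self, default_data):
        a = he.fit_reml(default_data, SPEC_DE_DMD_FULL)
        b = he.fit_reml(default_data, ModelSpec(response="DE", fixed=("OMD",),
                                                random=("season",)))
        with pytest.raises(DomainError):
            he.compare_random_structures(a, b)

    def test_large_season_effect_is_detected(self):
        """Power: a large injected season variance is picked up at alpha=0.05."""
        eq = {e.id: e for e in he.load_builtin_registry("table2")}["1a"]
        full_spec = ModelSpec(response="DE", fixed=("DMD",), random=("season",))
        red_spec = ModelSpec(response="DE", fixed=("DMD",), random=())
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            cfg = he.GeneratorConfig(seed=2000 + i)
            cfg.random_effect_var = {"season": 4.0}
            frame = he.generate_from_equation(eq, cfg, noise_sd=0.5)
            p = he.compare_random_structures(he.fit_reml(frame, full_spec),
                                             he.fit_reml(frame, red_spec))[2]
            hits += p < 0.05
        assert hits / n_rep >= 0.90

    def test_null_rejection_rate_is_conservative(self):
        """Type I: with no group effect, rejections at nominal 0.05 stay at
        or below 0.10 (the zero-boundary makes the chi-square reference
        conservative)."""
        eq = {e.id: e for e in he.load_builtin_registry("table2")}["1a"]
        full_spec = ModelSpec(response="DE", fixed=("DMD",), random=("season",))
        red_spec = ModelSpec(response="DE", fixed=("DMD",), random=())
        hits = 0
        n_rep = 500
        for i in range(n_rep):
            frame = he.generate_from_equation(
                eq, he.GeneratorConfig(seed=5000 + i), noise_sd=0.5)
            p = he.compare_random_structures(he.fit_reml(frame, full_spec),
                                             he.fit_reml(frame, red_spec))[2]
            hits += p < 0.05
        assert hits / n_rep <= 0.10


class TestWald:
    def test_statistic_is_squared_z_with_chi2_reference(self, default_data):
        from scipy import stats
        fit = he.fit_reml(default_data, SPEC_DE_DMD)
        est, se = fit.coefficients["DMD"], fit.std_errors["DMD"]
        stat, p = he.wald_test(fit, "DMD")
        assert stat == pytest.approx((est / se) ** 2, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(stat, 1), rel=1e-12)
        # an estimate at exactly 1.96 SEs would sit at the two-sided 5 % point
        assert stats.chi2.sf((est / se) ** 2, 1) == pytest.approx(
            2 * stats.norm.sf(abs(est / se)), rel=1e-9)

    def test_unknown_term_rejected(self, default_data):
        fit = he.fit_reml(default_data, SPEC_DE_DMD)
        with pytest.raises(DomainError):
            he.wald_test(fit, "NDF")


class TestDevelopEquation:
    def test_exact_recovery_without_noise(self, default_data):
        eq = {e.id: e for e in he.load_builtin_registry("table2")}["1a"]
        frame = he.generate_from_equation(eq, he.GeneratorConfig(seed=4),
                                          noise_sd=0.0)
        refit = he.develop_equation(frame, SPEC_DE_DMD_FULL)
        assert refit.intercept == pytest.approx(-0.527, abs=1e-6)
        assert refit.terms[0].coefficient == pytest.approx(18.552, abs=1e-6)
        assert refit.source == "refit"

    def test_no_random_structure_equals_ols(self, default_data):
        rng = np.random.default_rng(12)
        frame = default_data.copy()
        frame["de"] = 3.0 + 12.0 * frame["dmd"] + rng.normal(0, 0.3, len(frame))
        developed = he.develop_equation(frame, SPEC_DE_DMD_FULL)
        beta = _ols(frame, "de", ["dmd"])
        assert developed.intercept == pytest.approx(beta[0], rel=1e-6)
        assert developed.terms[0].coefficient == pytest.approx(beta[1], rel=1e-6)
        assert "retained: none" in developed.notes

    def test_absent_predictor_is_an_error(self, default_data):
        spec = ModelSpec(response="DE", fixed=("DMD",), random=())
        with pytest.raises(DomainError, match="DMD"):
            he.develop_equation(default_data.drop(columns=["dmd"]), spec)

    def test_injected_trial_effect_is_retained(self):
        eq = {e.id: e for e in he.load_builtin_registry("table2")}["1a"]
        cfg = he.GeneratorConfig(seed=77)
        cfg.random_effect_var = {"trial": 2.0}
        frame = he.generate_from_equation(eq, cfg, noise_sd=0.3)
        developed = he.develop_equation(
            frame, ModelSpec(response="DE", fixed=("DMD",), random=("trial",)))
        assert "retained: trial" in developed.notes
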