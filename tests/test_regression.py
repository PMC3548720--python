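"""Censored likelihood, MLE, and Wald inference for the PH regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import hypertabph as ht
from hypertabph.families import get_family
from hypertabph.regression import numeric_hessian


def make_data(time, event, **cols):
    return ht.SurvivalData(
        time=np.asarray(time, dtype=float),
        event=np.asarray(event),
        covariates=pd.DataFrame(cols) if cols else pd.DataFrame(index=range(len(time))),
    )


class TestClosedFormPieces:
    def test_relative_risk_identity_and_additivity(self):
        assert ht.relative_risk([0.3, -1.2], [0.0, 0.0]) == 1.0
        a, b = 0.4, -0.9
        assert ht.relative_risk([1.0, 1.0], [a, b]) == pytest.approx(
            np.exp(a) * np.exp(b), rel=1e-14
        )

    def test_relative_risk_reported_signature_effect(self):
        # one-unit change in the binary signature multiplies hazard ~3.32-fold
        assert ht.relative_risk([1.0], [1.199]) == pytest.approx(3.316, rel=1e-3)

    def test_relative_risk_dimension_mismatch(self):
        with pytest.raises(ValueError):
            ht.relative_risk([1.0, 2.0], [0.5])

    def test_ph_survival_reduces_to_baseline_and_powers(self, study_spec, unit_params):
        spec0 = ht.PHModelSpec("hypertabastic", (1.0, 1.0), {"z": 0.0})
        assert ht.ph_survival(1.0, [0.7], spec0) == pytest.approx(
            ht.baseline_survival(1.0, unit_params), rel=1e-14
        )
        spec1 = ht.PHModelSpec("hypertabastic", (1.0, 1.0), {"z": np.log(2.0)})
        assert ht.ph_survival(1.0, [1.0], spec1) == pytest.approx(
            ht.baseline_survival(1.0, unit_params) ** 2, rel=1e-12
        )
        spec2 = ht.PHModelSpec("hypertabastic", (1.0, 1.0), {"z": np.log(3.316)})
        assert ht.ph_survival(1.0, [1.0], spec2) == pytest.approx(
            0.952928 ** 3.316, rel=1e-5
        )

    def test_ph_hazard_proportionality(self):
        spec = ht.PHModelSpec("hypertabastic", (0.7, 0.6), {"z": 0.8})
        ratios = [
            float(ht.ph_hazard(t, [1.5], spec) / ht.ph_hazard(t, [-0.5], spec))
            for t in (1.0, 5.0, 20.0)
        ]
        assert ratios[0] == pytest.approx(np.exp(0.8 * 2.0), rel=1e-12)
        assert max(ratios) - min(ratios) < 1e-12

    def test_ph_hazard_scales_baseline(self, unit_params):
        spec = ht.PHModelSpec("hypertabastic", (1.0, 1.0), {"z": np.log(2.0)})
        assert ht.ph_hazard(1.0, [1.0], spec) == pytest.approx(
            2 * ht.baseline_hazard(1.0, unit_params), rel=1e-12
        )


class TestReportedInferenceArithmetic:
    """The printed estimate/SE columns reproduce the printed Wald/HR columns."""

    @pytest.mark.parametrize(
        "estimate,se,printed_wald",
        [
            (0.7247, 0.2888, 6.298),
            (0.6205, 0.1244, 24.873),
            (-0.07350, 0.01480, 24.645),
            (1.199, 0.3872, 9.585),
            (2.661, 0.7025, 14.343),
            (1.561, 0.7285, 4.594),
        ],
    )
    def test_wald_statistics(self, estimate, se, printed_wald):
        assert ht.wald_statistic(estimate, se) == pytest.approx(
            printed_wald, rel=5e-3
        )

    @pytest.mark.parametrize(
        "estimate,printed_hr",
        [(-0.07350, 0.9291), (1.199, 3.316), (2.661, 14.305), (1.561, 4.766)],
    )
    def test_hazard_ratios(self, estimate, printed_hr):
        assert ht.hazard_ratio(estimate) == pytest.approx(printed_hr, rel=1e-3)

    def test_wald_null_and_domain(self):
        assert ht.wald_statistic(0.0, 2.0) == 0.0
        assert ht.wald_p(0.0) == 1.0
        assert ht.wald_p(6.298) == pytest.approx(0.01209, rel=1e-3)
        with pytest.raises(ValueError):
            ht.wald_statistic(1.0, 0.0)
        with pytest.raises(ValueError):
            ht.wald_p(-1.0)

    def test_aic_consistency_with_reported_rows(self):
        assert ht.aic(-387.755 / 2, 6) == pytest.approx(399.755, abs=1e-9)
        assert ht.aic(-399.000 / 2, 6) == pytest.approx(411.000, abs=1e-9)
        assert ht.aic(0.0, 1) == 2.0
        with pytest.raises(ValueError):
            ht.aic(0.0, 0)


class TestLogLikelihood:
    def test_single_censored_subject_is_log_survival(self, unit_params):
        data = make_data([3.0], [0], z=[0.0])
        spec = ht.PHModelSpec("hypertabastic", (1.0, 1.0), {"z": 0.0})
        assert ht.log_likelihood(data, spec) == pytest.approx(
            ht.log_baseline_survival(3.0, unit_params), rel=1e-12
        )

    def test_single_event_subject_is_log_density(self, unit_params):
        data = make_data([3.0], [1], z=[0.0])
        spec = ht.PHModelSpec("hypertabastic", (1.0, 1.0), {"z": 0.0})
        assert ht.log_likelihood(data, spec) == pytest.approx(
            np.log(ht.baseline_density(3.0, unit_params)), rel=1e-12
        )

    @pytest.mark.parametrize("family", ["hypertabastic", "weibull", "loglogistic"])
    def test_matches_per_subject_product_oracle(self, family, rng):
        # brute force: likelihood as a product of f(t)^d * S(t)^(1-d) per
        # subject, each factor from scalar closed forms, then log
        n = 25
        time = rng.uniform(0.2, 15.0, n)
        event = (rng.uniform(size=n) < 0.6).astype(int)
        x1 = rng.normal(size=n)
        x2 = rng.uniform(-1, 1, n)
        data = make_data(time, event, a=x1, b=x2)
        spec = ht.PHModelSpec(family, (0.5, 0.8), {"a": 0.3, "b": -0.7})
        fam = get_family(family)
        total = 0.0
        for i in range(n):
            g = np.exp(0.3 * x1[i] - 0.7 * x2[i])
            s = np.exp(g * float(np.asarray(fam.log_sf(np.array([time[i]]), (0.5, 0.8)))[0]))
            h = g * float(np.asarray(fam.hazard(np.array([time[i]]), (0.5, 0.8)))[0])
            total += np.log(h * s) if event[i] else np.log(s)
        assert ht.log_likelihood(data, spec) == pytest.approx(total, abs=1e-8)


class TestFitting:
    def test_parameter_recovery_no_censoring(self):
        truth = ht.TrueModel(
            baseline=ht.HypertabasticParams(0.9, 0.8),
            coefficients={"z1": 0.7, "z2": -0.5},
        )
        rng = np.random.default_rng(77)
        n = 2000
        X = pd.DataFrame({"z1": rng.normal(size=n), "z2": rng.uniform(-1, 1, n)})
        t = ht.simulate_event_times(X, truth, seed=78)
        data = ht.SurvivalData(time=t, event=np.ones(n, dtype=int), covariates=X)
        fit = ht.fit_ph(data)
        assert fit.converged
        z = (fit.estimates - truth.param_values) / fit.se
        assert np.all(np.abs(z) < 3.0)

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(5)
        n = 50
        z = rng.normal(size=n)
        data = make_data(rng.uniform(1, 10, n), np.ones(n, dtype=int), a=z, b=z)
        with pytest.raises(ValueError, match="collinear"):
            ht.fit_ph(data)

    def test_constant_covariate_rejected(self):
        rng = np.random.default_rng(6)
        n = 50
        data = make_data(rng.uniform(1, 10, n), np.ones(n, dtype=int), a=np.ones(n))
        with pytest.raises(ValueError, match="constant"):
            ht.fit_ph(data)

    def test_too_few_subjects_or_events_rejected(self):
        with pytest.raises(ValueError):
            ht.fit_ph(make_data([1, 2, 3], [1, 1, 1], z=[0.1, 0.5, 0.9]))
        rng = np.random.default_rng(7)
        data = make_data(rng.uniform(1, 5, 20), np.zeros(20, dtype=int),
                         z=rng.normal(size=20))
        with pytest.raises(ValueError):
            ht.fit_ph(data)

    def test_nesting_likelihood_never_decreases(self, synth_cohort):
        sub = ht.fit_ph(synth_cohort, covariates=["AGE", "CSR"])
        full = ht.fit_ph(synth_cohort, covariates=["AGE", "CSR", "70G"])
        assert full.loglik >= sub.loglik - 1e-6
        null = ht.fit_ph(synth_cohort, covariates=[])
        assert sub.loglik >= null.loglik - 1e-6

    def test_rescaling_invariance(self, synth_cohort):
        fit = ht.fit_ph(synth_cohort, covariates=["AGE", "CSR"])
        scaled = synth_cohort.covariates.copy()
        scaled["AGE"] = scaled["AGE"] * 10.0
        data2 = ht.SurvivalData(synth_cohort.time, synth_cohort.event, scaled)
        fit2 = ht.fit_ph(data2, covariates=["AGE", "CSR"])
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-6)
        assert fit2.spec.coefficients["AGE"] == pytest.approx(
            fit.spec.coefficients["AGE"] / 10.0, rel=1e-4
        )

    def test_fit_result_internal_consistency(self, synth_fit):
        r = synth_fit
        assert r.aic == pytest.approx(r.minus_two_loglik + 2 * r.n_params, abs=1e-12)
        np.testing.assert_allclose(r.wald, (r.estimates / r.se) ** 2, rtol=1e-12)
        np.testing.assert_allclose(
            r.hazard_ratio, np.exp(r.estimates[2:]), rtol=1e-12
        )
        np.testing.assert_allclose(r.covariance, r.covariance.T, atol=1e-10)
        assert np.all(np.diag(r.covariance) >= 0)

    def test_returned_optimum_beats_start(self, synth_cohort):
        fit = ht.fit_ph(synth_cohort)
        start = ht.PHModelSpec(
            "hypertabastic", (0.5, 1.0), {k: 0.0 for k in synth_cohort.names}
        )
        assert fit.loglik >= ht.log_likelihood(synth_cohort, start)


class TestExponentialClosedForm:
    def test_weibull_profile_at_unit_shape_matches_closed_form(self):
        # with the Weibull shape pinned at 1 the model is exponential and
        # the MLE of the rate is events / total follow-up time
        rng = np.random.default_rng(123)
        n = 400
        t_event = rng.exponential(4.0, n)
        censor = rng.uniform(0, 12.0, n)
        time = np.minimum(t_event, censor)
        event = (t_event <= censor).astype(int)
        data = make_data(np.maximum(time, 1e-9), event)
        closed = event.sum() / time.sum()

        def negll(loglam):
            spec = ht.PHModelSpec("weibull", (np.exp(loglam), 1.0), {})
            return -ht.log_likelihood(data, spec)

        res = optimize.minimize_scalar(negll, bounds=(-8, 4), method="bounded",
                                       options={"xatol": 1e-12})
        assert np.exp(res.x) == pytest.approx(closed, rel=1e-4)


class TestCovariance:
    def test_numeric_hessian_exact_on_quadratic(self):
        A = np.array([[2.0, 0.4, 0.0], [0.4, 1.5, -0.3], [0.0, -0.3, 3.0]])

        def quad(x):
            return -0.5 * x @ A @ x

        H = numeric_hessian(quad, np.array([0.3, -0.2, 1.0]))
        np.testing.assert_allclose(H, -A, atol=1e-6)
        np.testing.assert_allclose(np.linalg.inv(-H), np.linalg.inv(A), atol=1e-6)

    def test_se_calibrated_against_replicate_spread(self):
        # estimated SEs should track the empirical SD of the estimates
        summary, _ = ht.recovery_experiment(
            truth=ht.default_true_model(),
            config=ht.CohortConfig(n=1000),
            n_values=(1000,),
            replicates=25,
            seed=314,
        )
        ratio = summary["mean_se"] / summary["empirical_sd"]
        assert np.all(ratio > 0.7) and np.all(ratio < 1.4)


class TestSklearnInterface:
    def test_get_set_params_and_clone(self):
        from sklearn.base import clone

        est = ht.ParametricPH(family="weibull", n_starts=3)
        params = est.get_params()
        assert params["family"] == "weibull" and params["n_starts"] == 3
        est2 = clone(est).set_params(family="hypertabastic")
        assert est2.get_params()["family"] == "hypertabastic"

    def test_fit_with_structured_survival_array(self, synth_cohort):
        y = np.empty(
            synth_cohort.n, dtype=[("event", "?"), ("time", "<f8")]
        )
        y["event"] = synth_cohort.event.astype(bool)
        y["time"] = synth_cohort.time
        est = ht.ParametricPH().fit(synth_cohort.covariates, y)
        assert est.converged_
        assert est.coef_.shape == (4,)
        assert list(est.feature_names_in_) == synth_cohort.names

    def test_predictions_shapes_and_monotonicity(self, synth_cohort):
        est = ht.ParametricPH().fit(
            synth_cohort.covariates, (synth_cohort.time, synth_cohort.event)
        )
        times = np.array([1.0, 5.0, 10.0, 20.0])
        S = est.predict_survival(synth_cohort.covariates.head(7), times)
        assert S.shape == (7, 4)
        assert np.all((S > 0) & (S <= 1))
        assert np.all(np.diff(S, axis=1) < 0)
        H = est.predict_cumulative_hazard(synth_cohort.covariates.head(7), times)
        np.testing.assert_allclose(S, np.exp(-H), rtol=1e-12)
        risk = est.predict(synth_cohort.covariates)
        assert risk.shape == (synth_cohort.n,)

    def test_score_is_mean_loglik(self, synth_cohort, synth_fit):
        est = ht.ParametricPH().fit(
            synth_cohort.covariates, (synth_cohort.time, synth_cohort.event)
        )
        score = est.score(synth_cohort.covariates, (synth_cohort.time, synth_cohort.event))
        assert score == pytest.approx(synth_fit.loglik / synth_cohort.n, rel=1e-9)


class TestCoxCrossCheck:
    def test_coefficients_agree_with_partial_likelihood(self, synth_cohort):
        # independent semi-parametric route: Cox partial likelihood makes no
        # use of the baseline family, yet must see the same covariate effects
        lifelines = pytest.importorskip("lifelines")
        frame = synth_cohort.covariates.copy()
        frame["T"] = synth_cohort.time
        frame["E"] = synth_cohort.event
        cox = lifelines.CoxPHFitter().fit(frame, duration_col="T", event_col="E")
        fit = ht.fit_ph(synth_cohort)
        for name in synth_cohort.names:
            ours = fit.spec.coefficients[name]
            theirs = cox.params_[name]
            se = max(fit.se[fit.param_names.index(name)], cox.standard_errors_[name])
            assert abs(ours - theirs) < 3.5 * se
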