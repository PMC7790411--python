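import numpy as np
import pytest

import implantsurv as im
from implantsurv.cohort import DesignMatrix, build_design
from implantsurv.parametric import (FamilyError, fit_parametric,
                                    loglik_parametric, predict_parametric)


def _null_design(cohort):
    return DesignMatrix(np.zeros((len(cohort), 0)), (), ())


class TestLoglik:
    def test_exponential_mle_is_events_over_person_time(self, small_cohort):
        cohort, _ = small_cohort
        fit = fit_parametric(cohort, "exponential", "PH",
                             design=_null_design(cohort),
                             compute_null=False, compute_covariance=False)
        lam = np.exp(fit.ancillary["log_lambda"])
        assert lam == pytest.approx(cohort.n_events / cohort.person_time,
                                    rel=1e-5)

    def test_weibull_with_unit_shape_equals_exponential(self, small_cohort):
        cohort, _ = small_cohort
        design = build_design(cohort)
        rng = np.random.default_rng(0)
        beta = rng.normal(0, 0.2, 14)
        p_exp = np.concatenate([[np.log(2e-4)], beta])
        p_wei = np.concatenate([[np.log(2e-4), 0.0], beta])
        assert loglik_parametric(p_wei, cohort, "weibull", "PH") == pytest.approx(
            loglik_parametric(p_exp, cohort, "exponential", "PH"), abs=1e-9)

    def test_gamma_frailty_closed_form_matches_quadrature(self, clustered_cohort):
        from scipy.integrate import quad
        from scipy.stats import gamma as gamma_dist

        cohort, _ = clustered_cohort
        keep = cohort.cluster_codes < 8
        sub = cohort.subset(keep)
        design = build_design(sub)
        rng = np.random.default_rng(2)
        theta = 0.4
        params = np.concatenate([[np.log(1e-4), 0.2],
                                 rng.normal(0, 0.2, 14), [np.log(theta)]])
        ll = loglik_parametric(params, sub, "weibull", "PH", "gamma", design)

        lam, gam = np.exp(params[0]), np.exp(params[1])
        beta = params[2:16]
        X, t, d, cl = design.values, sub.exit, sub.event, sub.cluster_codes
        ll_num = 0.0
        for g in range(sub.n_clusters):
            m = cl == g
            H = lam * t[m] ** gam * np.exp(X[m] @ beta)
            logh = np.log(lam * gam) + (gam - 1) * np.log(t[m]) + X[m] @ beta
            D = d[m].sum()

            def log_integrand(a):
                return (np.sum(d[m] * logh) + D * np.log(a) - a * H.sum()
                        + gamma_dist.logpdf(a, 1 / theta, scale=theta))

            mode = (D + 1 / theta - 1) / (H.sum() + 1 / theta)
            peak = log_integrand(mode)
            val, _ = quad(lambda a: np.exp(log_integrand(a) - peak), 0,
                          np.inf, limit=400, epsabs=1e-13, epsrel=1e-12)
            ll_num += peak + np.log(val)
        assert ll == pytest.approx(ll_num, abs=1e-8)

    def test_normal_intercept_marginal_matches_quadrature(self, clustered_cohort):
        from scipy.integrate import quad
        from scipy.stats import norm

        cohort, _ = clustered_cohort
        sub = cohort.subset(cohort.cluster_codes < 6)
        design = build_design(sub)
        rng = np.random.default_rng(3)
        tau2 = 0.3
        params = np.concatenate([[7.5, 0.1], rng.normal(0, 0.2, 14),
                                 [np.log(tau2)]])
        ll = loglik_parametric(params, sub, "lognormal", "AFT", "normal", design)
        mu, sig = params[0], np.exp(params[1])
        beta = params[2:16]
        X, t, d, cl = design.values, sub.exit, sub.event, sub.cluster_codes
        tau = np.sqrt(tau2)
        ll_num = 0.0
        for g in range(sub.n_clusters):
            m = cl == g

            def integrand(u):
                z = (np.log(t[m]) - (mu + X[m] @ beta + u)) / sig
                logf = norm.logpdf(z) - np.log(sig) - np.log(t[m])
                logS = norm.logsf(z)
                return np.exp(np.sum(d[m] * logf + (1 - d[m]) * logS)) * \
                    norm.pdf(u, 0, tau)

            val, _ = quad(integrand, -8 * tau, 8 * tau, limit=200)
            ll_num += np.log(val)
        assert ll == pytest.approx(ll_num, abs=1e-5)

    def test_invalid_family_parameterization_rejected(self, small_cohort):
        with pytest.raises(FamilyError):
            loglik_parametric(np.zeros(16), small_cohort[0], "lognormal", "PH")


class TestFitIdentities:
    def test_exponential_aft_is_sign_flipped_ph(self, small_cohort):
        cohort, _ = small_cohort
        ph = fit_parametric(cohort, "exponential", "PH",
                            compute_null=False, compute_covariance=False)
        aft = fit_parametric(cohort, "exponential", "AFT",
                             compute_null=False, compute_covariance=False)
        assert aft.loglik == pytest.approx(ph.loglik, abs=1e-5)
        assert np.abs(aft.beta + ph.beta).max() < 1e-4

    def test_weibull_aft_ph_reparameterization(self, small_cohort):
        cohort, _ = small_cohort
        ph = fit_parametric(cohort, "weibull", "PH",
                            compute_null=False, compute_covariance=False)
        aft = fit_parametric(cohort, "weibull", "AFT",
                             compute_null=False, compute_covariance=False)
        gam = np.exp(ph.ancillary["log_gamma"])
        assert aft.loglik == pytest.approx(ph.loglik, abs=1e-5)
        assert np.abs(aft.beta + ph.beta / gam).max() < 1e-3

    def test_weibull_nests_exponential(self, small_cohort):
        cohort, _ = small_cohort
        exp_ = fit_parametric(cohort, "exponential", "PH",
                              compute_null=False, compute_covariance=False)
        wei = fit_parametric(cohort, "weibull", "PH",
                             compute_null=False, compute_covariance=False)
        assert wei.loglik >= exp_.loglik - 1e-8

    def test_recovers_weibull_truth(self):
        from implantsurv.cohort import CovariateSpec

        cfg = im.SyntheticConfig(
            n_patients=500, frailty_theta=0.0, seed=55,
            covariate_spec=CovariateSpec(categories={"g": ("A", "B")},
                                         references={"g": "A"}),
            covariate_margins={"g": (0.5, 0.5)},
            true_log_hr={"g=B": float(np.log(2.0))},
            baseline=im.WeibullBaseline(2e-5, 1.3),
        )
        cohort, _ = im.generate(cfg)
        fit = fit_parametric(cohort, "weibull", "PH", compute_null=False,
                             compute_covariance=False)
        assert np.exp(fit.beta[0]) == pytest.approx(2.0, rel=0.10)
        assert np.exp(fit.ancillary["log_gamma"]) == pytest.approx(1.3, rel=0.10)

    def test_frailty_theta_near_zero_matches_fixed_effects(self, small_cohort):
        cohort, _ = small_cohort
        design = build_design(cohort)
        fe = fit_parametric(cohort, "weibull", "PH", design=design,
                            compute_null=False, compute_covariance=False)
        params = np.concatenate([
            [fe.ancillary["log_lambda"], fe.ancillary["log_gamma"]],
            fe.beta, [np.log(1e-10)],
        ])
        ll = loglik_parametric(params, cohort, "weibull", "PH", "gamma", design)
        assert ll == pytest.approx(fe.loglik, abs=1e-5)


class TestPredict:
    def test_survival_identity_and_boundary(self, small_cohort):
        cohort, _ = small_cohort
        fit = fit_parametric(cohort, "weibull", "PH", compute_null=False,
                             compute_covariance=False)
        t = np.logspace(-3, 3.5, 60)
        cur = predict_parametric(fit, {"periodontal": "Periodontitis"}, t)
        assert np.allclose(cur["survival"], np.exp(-cur["cumhaz"]))
        assert cur["survival"][0] == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.diff(cur["cumhaz"]) >= 0)

    def test_exponential_hazard_constant(self, small_cohort):
        fit = fit_parametric(small_cohort[0], "exponential", "PH",
                             compute_null=False, compute_covariance=False)
        cur = predict_parametric(fit, {}, np.array([10.0, 100.0, 1000.0]))
        assert np.allclose(cur["hazard"], cur["hazard"][0])
        lam = np.exp(fit.ancillary["log_lambda"])
        assert np.allclose(cur["cumhaz"], lam * cur["time"])

    def test_gamma_frailty_marginal_tends_to_conditional(self, clustered_cohort):
        cohort, _ = clustered_cohort
        fit = fit_parametric(cohort, "weibull", "PH", frailty_kind="gamma",
                             compute_null=False, compute_covariance=False)
        t = np.linspace(100, 3000, 20)
        import dataclasses

        tiny = dataclasses.replace(fit, theta=1e-9)
        cond = predict_parametric(tiny, {}, t, marginal=False)
        marg = predict_parametric(tiny, {}, t, marginal=True)
        assert np.abs(marg["survival"] - cond["survival"]).max() < 1e-6

    def test_nonpositive_times_rejected(self, small_cohort):
        fit = fit_parametric(small_cohort[0], "exponential", "PH",
                             compute_null=False, compute_covariance=False)
        with pytest.raises(ValueError):
            predict_parametric(fit, {}, np.array([0.0, 1.0]))
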