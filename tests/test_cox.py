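import numpy as np
import pytest

import implantsurv as im
from implantsurv.cohort import Cohort, CovariateSpec, TimeToEventRecord, build_design
from implantsurv.cox import (fit_cox, fit_cox_frailty, partial_loglik,
                             ph_p_value, ph_test)

from conftest import brute_force_breslow


def _cohort_from_arrays(exit_, event, g, spec=None):
    spec = spec or CovariateSpec(categories={"g": ("A", "B")}, references={"g": "A"})
    recs = [
        TimeToEventRecord(f"s{i}", f"s{i}", 0.0, float(t), int(e),
                          {"g": "B" if x else "A"})
        for i, (t, e, x) in enumerate(zip(exit_, event, g))
    ]
    return Cohort(recs, spec)


class TestPartialLoglik:
    def test_null_value_is_log_risk_set_sizes(self, small_cohort):
        cohort, _ = small_cohort
        data_entry, data_exit, data_event = cohort.entry, cohort.exit, cohort.event
        ll0 = partial_loglik(np.zeros(14), cohort)
        expected = 0.0
        for t in np.unique(data_exit[data_event == 1]):
            d = int(np.sum((data_exit == t) & (data_event == 1)))
            r = int(np.sum((data_entry < t) & (data_exit >= t)))
            expected -= d * np.log(r)
        assert ll0 == pytest.approx(expected, abs=1e-10)

    def test_two_subject_hand_value(self):
        cohort = _cohort_from_arrays([1.0, 2.0], [1, 1], [0, 1])
        ll = partial_loglik(np.zeros(1), cohort)
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_matches_brute_force_with_ties(self):
        # 6 records, a tied failure time at t=3
        exit_ = [1.0, 3.0, 3.0, 4.0, 5.0, 6.0]
        event = [1, 1, 1, 0, 1, 0]
        g = [0, 1, 0, 1, 1, 0]
        cohort = _cohort_from_arrays(exit_, event, g)
        X = build_design(cohort).values
        rng = np.random.default_rng(0)
        for _ in range(5):
            beta = rng.normal(0, 1, 1)
            assert partial_loglik(beta, cohort) == pytest.approx(
                brute_force_breslow(cohort.entry, exit_, event, X, beta),
                abs=1e-10,
            )

    def test_invariant_to_monotone_time_rescaling(self, small_cohort):
        cohort, _ = small_cohort
        beta = np.full(14, 0.1)
        ll = partial_loglik(beta, cohort)
        warped = cohort.subset(np.ones(len(cohort), bool))
        warped.df["exit_time"] = np.sqrt(warped.df["exit_time"])
        assert partial_loglik(beta, warped) == pytest.approx(ll, abs=1e-9)


class TestFitCox:
    def test_recovers_true_hazard_ratio(self):
        cfg = im.SyntheticConfig(
            n_patients=2000, frailty_theta=0.0, seed=30,
            covariate_spec=CovariateSpec(categories={"g": ("A", "B")},
                                         references={"g": "A"}),
            covariate_margins={"g": (0.5, 0.5)},
            true_log_hr={"g=B": float(np.log(1.5))},
            baseline=im.WeibullBaseline(2e-4, 1.0),
        )
        cohort, _ = im.generate(cfg)
        fit = fit_cox(cohort)
        se = np.sqrt(fit.covariance[0, 0])
        assert abs(fit.beta[0] - np.log(1.5)) < 1.96 * se + 0.05

    def test_matches_reference_implementation(self, small_cohort):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        cohort, _ = small_cohort
        # distinct event times: Efron and Breslow coincide, so lifelines is a
        # valid independent oracle for the Breslow fit
        assert len(np.unique(cohort.exit[cohort.event == 1])) == cohort.n_events
        fit = fit_cox(cohort)
        X = build_design(cohort).values
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
        df["T"], df["E"] = cohort.exit, cohort.event
        ref = lifelines.CoxPHFitter().fit(df, "T", "E")
        assert np.abs(fit.beta - ref.params_.values).max() < 1e-4
        assert fit.loglik == pytest.approx(ref.log_likelihood_, abs=1e-6)

    def test_constant_column_flagged_and_ignored(self, two_level_spec):
        rng = np.random.default_rng(1)
        recs = [
            TimeToEventRecord(f"s{i}", f"s{i}", 0.0, float(t), 1, {"g": "A"})
            for i, t in enumerate(rng.exponential(10, 30))
        ]
        cohort = Cohort(recs, two_level_spec)
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_cox(cohort)
        assert fit.beta[0] == 0.0
        assert fit.loglik == pytest.approx(fit.loglik_null)

    def test_baseline_cumhaz_nondecreasing_from_zero(self, small_cohort):
        fit = fit_cox(small_cohort[0])
        assert fit.baseline_cumhaz[0] == 0.0
        assert np.all(np.diff(fit.baseline_cumhaz) >= 0)


class TestFrailty:
    def test_theta_zero_data_reduces_to_plain_cox(self, small_cohort):
        cohort, _ = small_cohort
        plain = fit_cox(cohort)
        frail = fit_cox_frailty(cohort)
        assert frail.theta < 0.05
        assert np.abs(frail.beta - plain.beta).max() < 1e-2

    def test_theta_recovery_from_clustered_data(self):
        ths = []
        for seed in (40, 41):
            cfg = im.SyntheticConfig(
                n_patients=300, implant_level=True,
                implants_per_patient=(4.0, 0.0, 4, 4),
                frailty_theta=0.5, seed=seed,
            )
            cohort, _ = im.generate(cfg)
            ths.append(fit_cox_frailty(cohort).theta)
        assert all(0.3 <= t <= 0.7 for t in ths)

    def test_inner_maximization_matches_direct_optimum(self):
        # fixed theta: EM solution of the penalised partial likelihood equals
        # direct numeric maximisation over (beta, v)
        from scipy.optimize import minimize

        from implantsurv.cox import _CoxData, _cox_quantities, _inner_em

        rng = np.random.default_rng(7)
        n = 12
        exit_ = rng.exponential(10, n)
        event = rng.integers(0, 2, n)
        event[:4] = 1
        g = rng.integers(0, 2, n)
        cluster = np.repeat(np.arange(4), 3)
        spec = CovariateSpec(categories={"g": ("A", "B")}, references={"g": "A"})
        recs = [
            TimeToEventRecord(f"s{i}", f"c{cluster[i]}", 0.0, float(exit_[i]),
                              int(event[i]), {"g": "B" if g[i] else "A"})
            for i in range(n)
        ]
        cohort = Cohort(recs, spec)
        X = build_design(cohort).values
        data = _CoxData(cohort.entry, cohort.exit, cohort.event, X)
        theta, G = 0.5, 4
        beta_em, v_em, *_ = _inner_em(data, cluster, G, theta,
                                      np.zeros(1), np.zeros(G))

        def neg_pen(params):
            beta, v = params[:1], params[1:]
            ll, *_ = _cox_quantities(data, beta, offset=v[cluster])
            return -(ll + np.sum((v - np.exp(v)) / theta))

        res = minimize(neg_pen, np.zeros(1 + G), method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 5000})
        assert neg_pen(np.concatenate([beta_em, v_em])) == pytest.approx(
            res.fun, abs=1e-6)

    def test_single_cluster_rejected(self, two_level_spec):
        recs = [
            TimeToEventRecord(f"s{i}", "c0", 0.0, float(i + 1), 1, {"g": "A"})
            for i in range(5)
        ]
        with pytest.raises(ValueError, match="clusters"):
            fit_cox_frailty(Cohort(recs, two_level_spec))


class TestPHTest:
    def test_reference_p_value(self):
        # chi2 = 5.50 on 4 df -> p = 0.240
        assert round(ph_p_value(5.50, 4), 3) == 0.240

    def test_zero_statistic_gives_p_one(self):
        assert ph_p_value(0.0, 3) == 1.0

    def test_p_value_in_unit_interval(self, small_cohort):
        cohort, _ = small_cohort
        res = ph_test(fit_cox(cohort), cohort)
        assert 0.0 <= res.p_value <= 1.0
        assert res.df == 14

    def test_column_subset_reduces_df(self, small_cohort):
        cohort, _ = small_cohort
        fit = fit_cox(cohort)
        res = ph_test(fit, cohort, columns=[0, 1, 2, 3])
        assert res.df == 4

    def test_rejects_frailty_fit(self, clustered_cohort):
        cohort, _ = clustered_cohort
        frail = fit_cox_frailty(cohort)
        with pytest.raises(ValueError):
            ph_test(frail, cohort)
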