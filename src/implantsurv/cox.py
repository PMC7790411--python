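"""Cox proportional hazards with optional shared gamma frailty.

Estimation is by Breslow-form partial likelihood over the ordered failure
times, with risk sets ``R_j = {k : entry_k < t_(j) <= exit_k}`` (delayed
entry supported).  Shared gamma frailty at the cluster level is fitted by
profile likelihood: for fixed frailty variance ``theta`` the log frailties
``v_i`` and ``beta`` maximise the penalised partial likelihood

    logL_Cox(beta, v) + sum_i (1/theta) (v_i - exp(v_i))

via an EM-type alternation, and the profile objective adds the gamma
normalising terms so a one-dimensional search over ``theta`` yields the MLE.
The proportional-hazards assumption test is the score test for a linear
time interaction of each coefficient, built from Schoenfeld residuals and
exact per-event risk-set variances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2 as chi2_dist

from .cohort import Cohort, DesignMatrix, build_design

logger = logging.getLogger(__name__)

THETA_MIN = 1e-8
THETA_MAX = 10.0


class ConvergenceError(RuntimeError):
    pass


@dataclass
class CoxFit:
    beta: np.ndarray
    covariance: np.ndarray
    loglik: float
    loglik_null: float
    theta: float
    log_frailties: np.ndarray
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    columns: tuple[str, ...]
    n_events: int
    warnings_: list[str] = field(default_factory=list)

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def summary(self):
        """Per-term HR, 95% Wald CI and p-value (Table-3 style layout)."""
        import pandas as pd
        from scipy.stats import norm

        se = np.sqrt(np.diag(self.covariance))
        z = np.divide(self.beta, se, out=np.zeros_like(self.beta), where=se > 0)
        return pd.DataFrame(
            {
                "term": self.columns,
                "coef": self.beta,
                "hr": np.exp(self.beta),
                "hr_low": np.exp(self.beta - 1.96 * se),
                "hr_high": np.exp(self.beta + 1.96 * se),
                "p": 2 * norm.sf(np.abs(z)),
            }
        )


# ---------------------------------------------------------------------------
# Risk-set machinery (counting-process form, Breslow ties)
# ---------------------------------------------------------------------------

def _suffix_sums_at(times_sorted, values, query):
    """sum of values[k] with times_sorted[k] >= query, via suffix cumsum."""
    suffix = np.concatenate([np.cumsum(values[::-1], axis=0)[::-1],
                             np.zeros((1,) + values.shape[1:])])
    idx = np.searchsorted(times_sorted, query, side="left")
    return suffix[idx]


class _CoxData:
    """Precomputed sort orders and event groupings for one analysis."""

    def __init__(self, entry, exit_, event, X):
        self.entry = np.asarray(entry, float)
        self.exit = np.asarray(exit_, float)
        self.event = np.asarray(event, int)
        self.X = np.asarray(X, float)
        if self.event.sum() < 1:
            raise ValueError("partial likelihood requires at least one event")
        self.n, self.p = self.X.shape
        # ordered distinct failure times and per-time failure groups
        ft = self.exit[self.event == 1]
        self.fail_times, inv = np.unique(ft, return_inverse=True)
        self.F = self.fail_times.size
        self.d = np.bincount(inv, minlength=self.F).astype(float)
        Xf = self.X[self.event == 1]
        self.sum_x_fail = np.zeros((self.F, self.p))
        np.add.at(self.sum_x_fail, inv, Xf)
        # sort orders for suffix sums
        self.exit_order = np.argsort(self.exit, kind="stable")
        self.exit_sorted = self.exit[self.exit_order]
        self.has_entry = bool(np.any(self.entry > 0))
        if self.has_entry:
            self.entry_order = np.argsort(self.entry, kind="stable")
            self.entry_sorted = self.entry[self.entry_order]

    def risk_sums(self, w, xw=None, xxw=None):
        """S0 (and optionally S1, S2) over risk sets at each failure time."""
        s0 = _suffix_sums_at(self.exit_sorted, w[self.exit_order], self.fail_times)
        if self.has_entry:
            s0 = s0 - _suffix_sums_at(
                self.entry_sorted, w[self.entry_order], self.fail_times
            )
        res = [s0]
        if xw is not None:
            s1 = _suffix_sums_at(self.exit_sorted, xw[self.exit_order], self.fail_times)
            if self.has_entry:
                s1 = s1 - _suffix_sums_at(
                    self.entry_sorted, xw[self.entry_order], self.fail_times
                )
            res.append(s1)
        if xxw is not None:
            s2 = _suffix_sums_at(self.exit_sorted, xxw[self.exit_order], self.fail_times)
            if self.has_entry:
                s2 = s2 - _suffix_sums_at(
                    self.entry_sorted, xxw[self.entry_order], self.fail_times
                )
            res.append(s2)
        return res


def _cox_quantities(data: _CoxData, beta, offset=None, need_hess=False):
    """Breslow partial loglik, gradient and (optionally) Hessian."""
    eta = data.X @ beta
    if offset is not None:
        eta = eta + offset
    # guard against overflow in exp
    shift = np.max(eta)
    w = np.exp(eta - shift)
    xw = data.X * w[:, None]
    xxw = None
    if need_hess:
        xxw = np.einsum("np,nq->npq", data.X, xw)
    sums = data.risk_sums(w, xw, xxw)
    s0 = sums[0]
    s1 = sums[1]
    loglik = float(
        np.sum(eta[data.event == 1]) - np.sum(data.d * (np.log(s0) + shift))
    )
    xbar = s1 / s0[:, None]
    grad = data.sum_x_fail.sum(axis=0) - (data.d[:, None] * xbar).sum(axis=0)
    hess = None
    vbar = None
    if need_hess:
        s2 = sums[2]
        vbar = s2 / s0[:, None, None] - np.einsum("jp,jq->jpq", xbar, xbar)
        hess = -np.einsum("j,jpq->pq", data.d, vbar)
    return loglik, grad, hess, s0, xbar, vbar, shift


def partial_loglik(beta, cohort: Cohort, design: DesignMatrix | None = None,
                   offset=None) -> float:
    """Breslow partial log-likelihood at ``beta`` for the cohort."""
    design = design or build_design(cohort)
    data = _CoxData(cohort.entry, cohort.exit, cohort.event, design.values)
    beta = np.asarray(beta, float)
    ll, *_ = _cox_quantities(data, beta, offset=offset)
    return ll


def _newton_cox(data: _CoxData, offset=None, beta0=None, tol=1e-8, max_iter=100):
    """Newton-Raphson with step halving on the partial likelihood."""
    p = data.p
    beta = np.zeros(p) if beta0 is None else np.array(beta0, float)
    ll, grad, hess, *_ = _cox_quantities(data, beta, offset, need_hess=True)
    for it in range(max_iter):
        if np.linalg.norm(grad, np.inf) < tol:
            break
        try:
            step = np.linalg.solve(-hess + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, hess_new, *_ = _cox_quantities(
                data, cand, offset, need_hess=True
            )
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise ConvergenceError(
                f"step halving failed at iteration {it} (loglik {ll:.6f})"
            )
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
    else:
        raise ConvergenceError(
            f"Newton iteration cap ({max_iter}) reached; |grad|="
            f"{np.linalg.norm(grad, np.inf):.3e}"
        )
    return beta, ll, grad, hess


def _breslow_baseline(data: _CoxData, beta, offset=None):
    """Breslow estimator: step heights d_j / S0_j at each failure time."""
    _, _, _, s0, _, _, shift = _cox_quantities(data, beta, offset)
    steps = data.d / (s0 * np.exp(shift))
    return data.fail_times, np.cumsum(steps)


def fit_cox(cohort: Cohort, strata: str | None = None,
            design: DesignMatrix | None = None) -> CoxFit:
    """Maximum partial likelihood fit of the Cox model (Breslow ties).

    ``strata`` names a covariate category whose levels get separate baseline
    hazards (the partial likelihood sums over strata).  Covariate columns
    with no variation are excluded from estimation (coefficient 0) with a
    warning.
    """
    design = design or build_design(cohort)
    X = design.values
    keep = X.std(axis=0) > 0
    warns = []
    if not keep.all():
        dropped = [c for c, k in zip(design.columns, keep) if not k]
        warns.append(f"constant covariate column(s) excluded: {dropped}")
        warnings.warn(warns[-1])
    Xk = X[:, keep]
    p_all = X.shape[1]

    if strata is None:
        parts = [np.ones(len(cohort), bool)]
    else:
        parts = [
            (cohort.df[strata] == lev).to_numpy()
            for lev in cohort.covariate_spec.categories[strata]
            if (cohort.df[strata] == lev).any()
        ]
    datas = [
        _CoxData(cohort.entry[m], cohort.exit[m], cohort.event[m], Xk[m])
        for m in parts
        if cohort.event[m].sum() >= 1
    ]
    if not datas:
        raise ValueError("no stratum contains an event")

    if Xk.shape[1] == 0:
        beta_k = np.zeros(0)
        ll = sum(_cox_quantities(d, beta_k)[0] for d in datas)
        ll0 = ll
        hess_tot = np.zeros((0, 0))
    else:
        # joint Newton across strata
        beta_k = np.zeros(Xk.shape[1])
        ll = None
        for it in range(100):
            grads = np.zeros(Xk.shape[1])
            hesss = np.zeros((Xk.shape[1],) * 2)
            ll_tot = 0.0
            for d in datas:
                l, g, h, *_ = _cox_quantities(d, beta_k, need_hess=True)
                ll_tot += l
                grads += g
                hesss += h
            if np.linalg.norm(grads, np.inf) < 1e-8:
                ll = ll_tot
                hess_tot = hesss
                break
            step = np.linalg.solve(-hesss + 1e-12 * np.eye(len(grads)), grads)
            scale = 1.0
            while scale > 1e-9:
                cand = beta_k + scale * step
                cand_ll = sum(_cox_quantities(d, cand)[0] for d in datas)
                if ll_tot is not None and cand_ll >= ll_tot - 1e-12:
                    break
                scale *= 0.5
            beta_k = beta_k + scale * step
        else:
            raise ConvergenceError("Cox Newton iteration cap reached")
        if np.any(np.abs(beta_k) > 50):
            warns.append("possible separation: |beta| > 50 (monotone likelihood)")
            warnings.warn(warns[-1])
        ll0 = sum(_cox_quantities(d, np.zeros_like(beta_k))[0] for d in datas)

    beta = np.zeros(p_all)
    beta[keep] = beta_k
    cov = np.zeros((p_all, p_all))
    if Xk.shape[1] > 0:
        cov_k = np.linalg.inv(-hess_tot)
        cov[np.ix_(keep, keep)] = cov_k

    # baseline cumulative hazard from the first (or only) stratum
    bt, bh = _breslow_baseline(datas[0], beta_k)
    return CoxFit(
        beta=beta,
        covariance=cov,
        loglik=float(ll),
        loglik_null=float(ll0),
        theta=0.0,
        log_frailties=np.zeros(cohort.n_clusters),
        baseline_times=np.concatenate([[0.0], bt]),
        baseline_cumhaz=np.concatenate([[0.0], bh]),
        columns=design.columns,
        n_events=cohort.n_events,
        warnings_=warns,
    )


# ---------------------------------------------------------------------------
# Shared gamma frailty by EM + profile likelihood
# ---------------------------------------------------------------------------

def _gamma_penalty_terms(theta, v, D):
    """Profile-likelihood correction terms for the gamma frailty.

    Algebraically equal to
    ``sum_i a(v_i - e^{v_i}) + (a + D_i)(1 - log(a + D_i)) - a log(theta)
    + lgamma(a + D_i) - lgamma(a)`` with ``a = 1/theta``; rewritten with
    ``expm1``/``log1p`` and the telescoped gamma ratio (integer event
    counts) so it stays accurate as ``theta -> 0``.
    """
    a = 1.0 / theta
    val = float(np.sum(a * (v - np.expm1(v)) + D - (a + D) * np.log1p(D * theta)))
    for j in range(1, int(np.max(D)) if len(D) else 0):
        val += float(np.log1p(j * theta) * np.count_nonzero(D > j))
    return val


def _step_eval(times, cumvals, t):
    """Right-continuous step function sum_{times_j <= t} increments."""
    idx = np.searchsorted(times, t, side="right")
    padded = np.concatenate([[0.0], cumvals])
    return padded[idx]


def _inner_em(data: _CoxData, cluster, G, theta, beta0, v0, max_iter=200, tol=1e-9):
    """For fixed theta, maximise the penalised partial likelihood in (beta, v)."""
    D = np.bincount(cluster, weights=data.event.astype(float), minlength=G)
    beta = np.array(beta0, float)
    v = np.array(v0, float)
    a = 1.0 / theta
    pen_ll_old = -np.inf
    for it in range(max_iter):
        offset = v[cluster]
        if data.p > 0:
            beta, ll, grad, hess = _newton_cox(data, offset=offset, beta0=beta)
        else:
            ll, grad, hess, *_ = _cox_quantities(data, beta, offset, need_hess=True)
        # expected cumulative hazard per cluster (excluding own frailty)
        bt, bh = _breslow_baseline(data, beta, offset=offset)
        H_at = _step_eval(bt, bh, data.exit)
        H0_at = _step_eval(bt, bh, data.entry)
        rel = np.exp(data.X @ beta)
        C = np.bincount(cluster, weights=rel * (H_at - H0_at), minlength=G)
        v_new = np.log((a + D) / (a + C))
        v = v_new
        pen_ll = ll + float(np.sum(a * (v - np.exp(v))))
        if abs(pen_ll - pen_ll_old) < tol * (1 + abs(pen_ll)):
            break
        pen_ll_old = pen_ll
    offset = v[cluster]
    ll, grad, hess, *_ = _cox_quantities(data, beta, offset, need_hess=(data.p > 0))
    return beta, v, ll, hess, D


def fit_cox_frailty(cohort: Cohort, design: DesignMatrix | None = None) -> CoxFit:
    """Cox model with shared gamma frailty, profile likelihood over theta.

    Frailties have mean 1 and variance ``theta``; the degree of within-cluster
    correlation is measured by the profiled ``theta`` (0 means no frailty).
    The reported covariance for ``beta`` conditions on the estimated log
    frailties (penalised-likelihood curvature), which slightly understates
    the frailty-induced uncertainty.
    """
    if cohort.n_clusters < 2:
        raise ValueError("frailty model requires at least 2 clusters")
    design = design or build_design(cohort)
    X = design.values
    keep = X.std(axis=0) > 0
    Xk = X[:, keep]
    data = _CoxData(cohort.entry, cohort.exit, cohort.event, Xk)
    cluster = cohort.cluster_codes
    G = cohort.n_clusters

    cache: dict[float, tuple] = {}
    state = {"beta": np.zeros(Xk.shape[1]), "v": np.zeros(G)}

    def profile(log_theta):
        theta = float(np.exp(log_theta))
        beta, v, ll, hess, D = _inner_em(
            data, cluster, G, theta, state["beta"], state["v"]
        )
        state["beta"], state["v"] = beta, v
        val = ll + _gamma_penalty_terms(theta, v, D)
        cache[theta] = (beta, v, ll, hess, D, val)
        return -val

    res = minimize_scalar(
        profile,
        bounds=(np.log(THETA_MIN), np.log(THETA_MAX)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    theta = float(np.exp(res.x))
    beta_k, v, ll_cox, hess, D, ll_profile = cache[theta]
    warns = []
    if theta > 0.99 * THETA_MAX:
        warns.append(f"profiled theta at upper bound {THETA_MAX}")
        warnings.warn(warns[-1])

    p_all = X.shape[1]
    beta = np.zeros(p_all)
    beta[keep] = beta_k
    cov = np.zeros((p_all, p_all))
    if Xk.shape[1] > 0:
        cov[np.ix_(keep, keep)] = np.linalg.inv(-hess)

    # null model: beta = 0 at the profiled theta (same frailty structure)
    _, v0, ll_null_cox, _, D0 = _inner_em(
        _CoxData(cohort.entry, cohort.exit, cohort.event, np.zeros((len(cohort), 0))),
        cluster, G, theta, np.zeros(0), np.zeros(G),
    )
    ll_null = ll_null_cox + _gamma_penalty_terms(theta, v0, D0)

    bt, bh = _breslow_baseline(data, beta_k, offset=v[cluster])
    return CoxFit(
        beta=beta,
        covariance=cov,
        loglik=float(ll_profile),
        loglik_null=float(ll_null),
        theta=theta,
        log_frailties=v,
        baseline_times=np.concatenate([[0.0], bt]),
        baseline_cumhaz=np.concatenate([[0.0], bh]),
        columns=design.columns,
        n_events=cohort.n_events,
        warnings_=warns,
    )


# ---------------------------------------------------------------------------
# Proportional-hazards assumption test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PHTestResult:
    chi2: float
    df: int
    p_value: float


def ph_p_value(chi2: float, df: int) -> float:
    """Upper-tail chi-squared probability for a PH test statistic."""
    if chi2 < 0 or df < 1:
        raise ValueError("chi2 must be >= 0 and df >= 1")
    return float(chi2_dist.sf(chi2, df))


def ph_test(fit: CoxFit, cohort: Cohort, columns=None,
            design: DesignMatrix | None = None) -> PHTestResult:
    """Global score test for proportional hazards (linear time interaction).

    Tests ``beta_j(t) = beta_j + phi_j * t`` (identity time transform) for
    the requested columns via Schoenfeld residuals, using exact per-event
    risk-set variances.  ``columns`` selects a subset of covariate columns
    (indices or labels); default tests all non-constant columns.
    """
    if fit.theta != 0:
        raise ValueError("PH test is defined for the plain Cox fit")
    design = design or build_design(cohort)
    X = design.values
    keep = X.std(axis=0) > 0
    Xk = X[:, keep]
    labels = [c for c, k in zip(design.columns, keep) if k]
    data = _CoxData(cohort.entry, cohort.exit, cohort.event, Xk)
    beta_k = fit.beta[np.asarray(keep)]
    if data.d.sum() <= len(beta_k):
        raise ValueError("fewer events than covariates; PH test undefined")

    _, _, _, s0, xbar, vbar, _ = _cox_quantities(data, beta_k, need_hess=True)
    s_j = data.sum_x_fail - data.d[:, None] * xbar          # Schoenfeld sums
    g = data.fail_times.copy()
    gbar = np.sum(data.d * g) / np.sum(data.d)
    g = (g - gbar) / np.std(g)                              # scaling is immaterial

    U = (g[:, None] * s_j).sum(axis=0)
    I_pp = np.einsum("j,jpq->pq", data.d * g * g, vbar)
    I_pb = np.einsum("j,jpq->pq", data.d * g, vbar)
    I_bb = np.einsum("j,jpq->pq", data.d, vbar)

    if columns is None:
        idx = np.arange(len(labels))
    else:
        idx = np.array(
            [c if isinstance(c, (int, np.integer)) else labels.index(c) for c in columns]
        )
    Us = U[idx]
    V = I_pp[np.ix_(idx, idx)] - I_pb[idx] @ np.linalg.solve(I_bb, I_pb[:, idx])
    stat = float(Us @ np.linalg.solve(V, Us))
    df = len(idx)
    return PHTestResult(chi2=stat, df=df, p_value=ph_p_value(stat, df))
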