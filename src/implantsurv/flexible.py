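"""Flexible parametric survival on the log-cumulative-hazard scale.

The model writes ``ln H(t | x) = s(ln t; gamma) + x beta`` where ``s`` is a
restricted cubic spline with ``df`` terms (plus intercept) built from the
uncensored log event times.  With ``df = 1`` the spline is linear in log
time and the model is exactly the Weibull PH model.  The log-likelihood of
record ``i`` with event indicator ``d_i`` is

    d_i (ln s'(ln t_i) + eta_i - ln t_i) - exp(eta_i)

(the hazard is ``h = s'(ln t) H / t``), plus, for delayed entry, the entry
cumulative hazard.  An optional shared gamma frailty at the cluster level is
marginalised in closed form; estimation is quasi-Newton on
``(gamma, beta, ln theta)`` with analytic gradients and a Weibull-based warm
start.  ``ln H`` is not constrained to be increasing during optimisation;
monotonicity (``s' > 0`` at the event times) is diagnosed at the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from ._frailty import (cluster_sums, gamma_marginal_dlogtheta,
                       gamma_marginal_terms, gamma_marginal_weights)
from .cohort import Cohort, DesignMatrix, build_design
from .splines import SplineBasis, orthogonalize, place_knots

logger = logging.getLogger(__name__)

_SP_EPS = 1e-10     # soft floor for log s' during optimisation
LOG_THETA_MIN = np.log(1e-8)
LOG_THETA_MAX = np.log(10.0)


class RPError(RuntimeError):
    pass


@dataclass
class RPFit:
    basis: SplineBasis
    gamma: np.ndarray            # spline coefficients incl. (transformed) intercept
    beta: np.ndarray
    theta: float
    loglik: float
    loglik_null: float
    covariance: np.ndarray       # over (gamma, beta[, log theta])
    columns: tuple[str, ...]
    n_events: int
    frailty: bool
    monotone_ok: bool
    warnings_: list[str] = field(default_factory=list)

    @property
    def df(self) -> int:
        return self.basis.df

    @property
    def n_parameters(self) -> int:
        return len(self.gamma) + len(self.beta) + (1 if self.frailty else 0)

    def eta(self, times, x=None) -> np.ndarray:
        """Linear predictor ln H(t|x) on a time grid."""
        logt = np.log(np.asarray(times, float))
        out = self.basis.design(logt) @ self.gamma
        if x is not None:
            out = out + float(np.asarray(x, float) @ self.beta)
        return out

    def spline_summary(self):
        """Exp-scale spline slopes with Wald CIs (the ``_rcs`` terms)."""
        import pandas as pd

        m = len(self.gamma)
        se = np.sqrt(np.clip(np.diag(self.covariance)[:m], 0, None))
        rows = []
        for j in range(1, m):
            z = self.gamma[j] / se[j] if se[j] > 0 else 0.0
            rows.append(
                {
                    "term": f"_rcs{j}",
                    "coef": self.gamma[j],
                    "ratio": np.exp(self.gamma[j]),
                    "ratio_low": np.exp(self.gamma[j] - 1.96 * se[j]),
                    "ratio_high": np.exp(self.gamma[j] + 1.96 * se[j]),
                    "p": 2 * norm.sf(abs(z)),
                }
            )
        return pd.DataFrame(rows)

    @property
    def spline_pvalues(self) -> np.ndarray:
        return self.spline_summary()["p"].to_numpy()

    def beta_summary(self):
        import pandas as pd

        m = len(self.gamma)
        se = np.sqrt(np.clip(np.diag(self.covariance)[m:m + len(self.beta)], 0, None))
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

    def theta_ci(self) -> tuple[float, float]:
        """Wald CI for theta on the log scale."""
        if not self.frailty:
            return (0.0, 0.0)
        idx = len(self.gamma) + len(self.beta)
        se = np.sqrt(max(self.covariance[idx, idx], 0.0))
        lt = np.log(self.theta)
        lo = np.clip(lt - 1.96 * se, -700, 700)
        hi = np.clip(lt + 1.96 * se, -700, 700)
        return (float(np.exp(lo)), float(np.exp(hi)))


# ---------------------------------------------------------------------------
# likelihood core
# ---------------------------------------------------------------------------

def _soft_log(sp):
    """log(sp) with a smooth linear extension below _SP_EPS (and its slope)."""
    sp = np.asarray(sp, float)
    lo = sp < _SP_EPS
    val = np.where(lo, np.log(_SP_EPS) + (sp - _SP_EPS) / _SP_EPS,
                   np.log(np.where(lo, 1.0, sp)))
    dval = np.where(lo, 1.0 / _SP_EPS, 1.0 / np.where(lo, 1.0, sp))
    return val, dval


class _RPData:
    """Precomputed arrays for one cohort/basis pair."""

    def __init__(self, cohort: Cohort, basis: SplineBasis, design: DesignMatrix):
        if np.any(cohort.exit <= 0):
            raise ValueError("all exit times must be positive")
        self.logt = np.log(cohort.exit)
        self.d = cohort.event.astype(float)
        self.B = basis.design(self.logt)
        self.Bp = basis.design_deriv(self.logt)
        self.X = design.values
        self.cluster = cohort.cluster_codes
        self.G = cohort.n_clusters
        self.D = cluster_sums(self.d, self.cluster, self.G)
        self.has_entry = bool(np.any(cohort.entry > 0))
        if self.has_entry:
            pos = cohort.entry > 0
            self.entry_pos = pos
            self.B0 = basis.design(np.log(cohort.entry[pos]))
        self.m = self.B.shape[1]
        self.p = self.X.shape[1]


def _rp_negll_grad(params, data: _RPData, frailty: bool):
    m, p = data.m, data.p
    gam = params[:m]
    beta = params[m:m + p]
    eta = data.B @ gam + data.X @ beta
    sp = data.Bp @ gam
    H = np.exp(np.clip(eta, -700, 700))
    logsp, dlogsp = _soft_log(sp)
    ev = data.d
    ll_events = float(np.sum(ev * (logsp + eta - data.logt)))

    if not frailty:
        ll = ll_events - float(np.sum(H))
        w = np.ones_like(H)
        if data.has_entry:
            eta0 = data.B0 @ gam + data.X[data.entry_pos] @ beta
            H0 = np.exp(np.clip(eta0, -700, 700))
            ll += float(np.sum(H0))
        ggam = (ev * dlogsp) @ data.Bp + (ev - H) @ data.B
        gbeta = (ev - H) @ data.X
        if data.has_entry:
            ggam += H0 @ data.B0
            gbeta += H0 @ data.X[data.entry_pos]
        return -ll, -np.concatenate([ggam, gbeta])

    logtheta = params[m + p]
    theta = float(np.exp(logtheta))
    A = cluster_sums(H, data.cluster, data.G)
    ll = ll_events + gamma_marginal_terms(theta, data.D, A)
    c = gamma_marginal_weights(theta, data.D, A)
    wrec = c[data.cluster] * H
    ggam = (ev * dlogsp) @ data.Bp + (ev - wrec) @ data.B
    gbeta = (ev - wrec) @ data.X
    gtheta = gamma_marginal_dlogtheta(theta, data.D, A)
    return -ll, -np.concatenate([ggam, gbeta, [gtheta]])


def rp_loglik(gamma, beta, cohort: Cohort, basis: SplineBasis,
              theta: float = 0.0, design: DesignMatrix | None = None) -> float:
    """(Marginal) log-likelihood of the spline model at given parameters.

    ``theta > 0`` uses the closed-form shared-gamma-frailty marginal over
    clusters.  Includes the ``-d ln t`` Jacobian term so values are directly
    comparable with the parametric families' log-likelihoods.
    """
    design = design or build_design(cohort)
    data = _RPData(cohort, basis, design)
    if theta > 0:
        if data.has_entry:
            raise ValueError("delayed entry is not supported with frailty")
        params = np.concatenate([gamma, beta, [np.log(theta)]])
        negll, _ = _rp_negll_grad(params, data, frailty=True)
    else:
        params = np.concatenate([gamma, beta])
        negll, _ = _rp_negll_grad(params, data, frailty=False)
    return -float(negll)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _weibull_warm_start(data: _RPData):
    """Crude exponential-based initial values for (gamma, beta)."""
    # ln H ~ ln(rate) + ln t on the raw scale; project onto the basis columns
    rate = max(data.d.sum(), 1.0) / np.sum(np.exp(data.logt))
    target = np.log(rate) + data.logt
    gam0, *_ = np.linalg.lstsq(data.B, target, rcond=None)
    return gam0


def fit_rp(cohort: Cohort, df: int, frailty: bool = False,
           design: DesignMatrix | None = None,
           use_orthogonal: bool = True,
           compute_null: bool = True,
           compute_covariance: bool = True,
           basis: SplineBasis | None = None,
           start: np.ndarray | None = None) -> RPFit:
    """Fit the flexible parametric model with ``df`` spline terms.

    Knots are placed at centiles of this cohort's uncensored log event times
    and the spline design is orthogonalised over those times (fit-invariant).
    The frailty variant requires at least two clusters and no delayed entry.
    """
    if frailty and cohort.n_clusters < 2:
        raise ValueError("frailty model requires at least 2 clusters")
    design = design or build_design(cohort)
    if basis is None:
        uncensored = np.log(cohort.exit[cohort.event == 1])
        if np.unique(uncensored).size < df + 1:
            raise RPError(f"need at least df+1={df + 1} distinct event times")
        basis = place_knots(df, uncensored)
        if use_orthogonal:
            basis = orthogonalize(basis, uncensored)
    data = _RPData(cohort, basis, design)

    if start is not None:
        x0 = np.asarray(start, float)
    else:
        gam0 = _weibull_warm_start(data)
        x0 = np.concatenate([gam0, np.zeros(data.p)])
        if frailty:
            x0 = np.concatenate([x0, [np.log(0.2)]])

    bounds = None
    if frailty:
        bounds = [(None, None)] * (data.m + data.p) + [(LOG_THETA_MIN, LOG_THETA_MAX)]
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        res = minimize(
            _rp_negll_grad, x0, args=(data, frailty), jac=True,
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 1000, "ftol": 1e-13, "gtol": 1e-8},
        )
        if not res.success:
            # L-BFGS can stall on the nearly flat log-theta direction near
            # the boundary; polish with damped Newton on the exact gradient
            res = _newton_polish(res, data, frailty, bounds)

    def _projected_grad(r):
        pg = np.asarray(r.jac, float).copy()
        if frailty:
            lt = r.x[-1]
            if (lt <= LOG_THETA_MIN + 1e-8 and pg[-1] > 0) or (
                lt >= LOG_THETA_MAX - 1e-8 and pg[-1] < 0
            ):
                pg[-1] = 0.0
        return pg

    # tolerance scaled to the information in the data: a gradient of this
    # size moves coefficients by O(1e-5), far below statistical noise
    gtol = 1e-5 * (1.0 + data.d.sum())
    if not res.success and np.linalg.norm(_projected_grad(res), np.inf) > gtol:
        raise RPError(f"flexible fit (df={df}) did not converge: {res.message}")
    x = res.x
    gam = x[:data.m]
    beta = x[data.m:data.m + data.p]
    theta = float(np.exp(x[data.m + data.p])) if frailty else 0.0
    ll = -float(res.fun)

    warns = []
    sp_events = (data.Bp @ gam)[data.d == 1]
    monotone_ok = bool(np.all(sp_events > 0))
    if not monotone_ok:
        warns.append(
            f"s'(ln t) <= 0 at {int(np.sum(sp_events <= 0))} event time(s); "
            "fitted cumulative hazard is not monotone there"
        )
        logger.warning("fit_rp df=%d: %s", df, warns[-1])

    cov = np.full((len(x), len(x)), np.nan)
    if compute_covariance:
        cov = _covariance_from_grad(x, data, frailty)

    ll_null = np.nan
    if compute_null:
        if data.p == 0:
            ll_null = ll
        else:
            null_design = DesignMatrix(np.zeros((len(cohort), 0)), (), ())
            nd = _RPData(cohort, basis, null_design)
            xn = np.concatenate([gam, [x[-1]]]) if frailty else gam.copy()
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                resn = minimize(_rp_negll_grad, xn, args=(nd, frailty), jac=True,
                                method="L-BFGS-B",
                                bounds=([(None, None)] * data.m
                                        + [(LOG_THETA_MIN, LOG_THETA_MAX)])
                                if frailty else None,
                                options={"maxiter": 1000, "ftol": 1e-13,
                                         "gtol": 1e-8})
            ll_null = -float(resn.fun)

    return RPFit(
        basis=basis, gamma=gam, beta=beta, theta=theta,
        loglik=ll, loglik_null=float(ll_null), covariance=cov,
        columns=design.columns, n_events=cohort.n_events,
        frailty=frailty, monotone_ok=monotone_ok, warnings_=warns,
    )


def _newton_polish(res, data, frailty, bounds, max_iter=15):
    """Damped Newton steps from a stalled quasi-Newton state."""
    x = np.asarray(res.x, float).copy()
    f, g = _rp_negll_grad(x, data, frailty)
    n = len(x)
    converged = False
    for _ in range(max_iter):
        if np.linalg.norm(g, np.inf) < 1e-9:
            converged = True
            break
        H = np.empty((n, n))
        for i in range(n):
            hi = 1e-6 * max(1.0, abs(x[i]))
            e = np.zeros(n); e[i] = hi
            _, gp = _rp_negll_grad(x + e, data, frailty)
            _, gm = _rp_negll_grad(x - e, data, frailty)
            H[i] = (gp - gm) / (2 * hi)
        H = 0.5 * (H + H.T)
        # freeze directions with (numerically) no curvature, e.g. log-theta
        # as theta -> 0, where the likelihood is flat by construction
        dia = np.abs(np.diag(H))
        active = dia > 1e-10 * dia.max()
        Ha = H[np.ix_(active, active)]
        ga = g[active]
        step = np.zeros(n)
        lam = 1e-8 * max(1.0, np.trace(Ha) / max(1, active.sum()))
        for _ in range(40):
            try:
                sa = np.linalg.solve(Ha + lam * np.eye(len(ga)), -ga)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            if sa @ ga < 0:
                step[active] = sa
                break
            lam *= 10
        # a negligible Newton displacement means the optimum is resolved to
        # below statistical noise even if the (noisy) objective cannot
        # certify further descent
        if np.max(np.abs(step)) < 1e-3:
            converged = True
        improved = False
        scale = 1.0
        for _ in range(30):
            cand = x + scale * step
            if bounds is not None:
                cand[-1] = np.clip(cand[-1], LOG_THETA_MIN, LOG_THETA_MAX)
            fc, gc = _rp_negll_grad(cand, data, frailty)
            if fc < f:
                x, f, g = cand, fc, gc
                improved = True
                break
            scale *= 0.5
        if converged or not improved:
            break
    res.x, res.fun, res.jac = x, f, g
    gchk = g.copy()
    if frailty and np.exp(x[-1]) < 1e-5:
        gchk[-1] = 0.0   # flat direction; theta is effectively at zero
    res.success = bool(
        converged
        or np.linalg.norm(gchk, np.inf) < 1e-5 * (1.0 + data.d.sum())
    )
    return res


def _covariance_from_grad(x, data, frailty, h=1e-6):
    """Observed information via central differences of the analytic gradient."""
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        hi = h * max(1.0, abs(x[i]))
        e = np.zeros(n); e[i] = hi
        _, gp = _rp_negll_grad(x + e, data, frailty)
        _, gm = _rp_negll_grad(x - e, data, frailty)
        H[i] = (gp - gm) / (2 * hi)
    H = 0.5 * (H + H.T)
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        logger.warning("singular information matrix in flexible fit")
        return np.full((n, n), np.nan)


def predict_rp(fit: RPFit, covariates, times, marginal: bool = False):
    """Hazard, cumulative hazard and survival on a time grid.

    ``marginal=True`` integrates the gamma frailty out:
    ``S_m = (1 + theta H)^(-1/theta)``; otherwise curves condition on
    frailty 1.
    """
    from .parametric import _pattern_vector

    times = np.asarray(times, float)
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    x = _pattern_vector(covariates, fit.columns)
    logt = np.log(times)
    eta = fit.basis.design(logt) @ fit.gamma + float(x @ fit.beta)
    sp = fit.basis.design_deriv(logt) @ fit.gamma
    H = np.exp(eta)
    S = np.exp(-H)
    h = sp * H / times
    if marginal and fit.frailty and fit.theta > 0:
        th = fit.theta
        S = (1.0 + th * H) ** (-1.0 / th)
        h = h / (1.0 + th * H)
        H = np.log1p(th * H) / th
    return {"time": times, "hazard": h, "cumhaz": H, "survival": S}


def df_ladder(cohort: Cohort, dfs, frailty: bool = False,
              design: DesignMatrix | None = None,
              compute_null: bool = True) -> list[RPFit]:
    """Fit the flexible model at each requested df; failures are logged.

    Fits are warm-started from the previous df's solution where possible.
    """
    design = design or build_design(cohort)
    uncensored = np.log(cohort.exit[cohort.event == 1])
    fits: list[RPFit] = []
    prev: RPFit | None = None
    for df in sorted(dfs):
        try:
            start = None
            basis = None
            if prev is not None:
                basis = place_knots(df, uncensored)
                basis = orthogonalize(basis, uncensored)
                # project the previous fitted spline onto the new basis so the
                # nested model starts at (numerically) its optimal value
                Bnew = basis.design(uncensored)
                target = prev.basis.design(uncensored) @ prev.gamma
                gam0, *_ = np.linalg.lstsq(Bnew, target, rcond=None)
                start = np.concatenate([gam0, prev.beta])
                if frailty:
                    start = np.concatenate([start, [np.log(max(prev.theta, 1e-8))]])
            fit = fit_rp(cohort, df=df, frailty=frailty, design=design,
                         compute_null=compute_null, basis=basis, start=start)
            if prev is not None and fit.loglik < prev.loglik - 1e-6:
                # retry from the default warm start; keep the better optimum
                alt = fit_rp(cohort, df=df, frailty=frailty, design=design,
                             compute_null=compute_null)
                if alt.loglik > fit.loglik:
                    fit = alt
            fits.append(fit)
            prev = fit
        except (RPError, ValueError) as exc:
            logger.warning("df ladder: df=%d failed (%s); continuing", df, exc)
    return fits
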