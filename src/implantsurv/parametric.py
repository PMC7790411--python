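"""Parametric survival families in PH and AFT form, with cluster random effects.

Families: exponential, Weibull, log-logistic, log-normal and generalized
gamma ("gamma").  The exponential and Weibull support both the proportional
hazards (PH) and accelerated failure time (AFT) parameterisations; the
log-logistic, log-normal and gamma are AFT-only.  Cluster-level random
effects come in two kinds:

* ``gamma`` — multiplicative mean-1 gamma frailty on the hazard (PH
  families), marginalised in closed form;
* ``normal`` — a normal random intercept on log time (AFT families),
  marginalised by Gauss-Hermite quadrature.

Censored-data log-likelihood: sum of ``d*log f + (1-d)*log S`` with delayed
entry handled by conditioning on survival to the entry time (frailty-free
fits only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, gammaincc
from scipy.stats import norm

from ._frailty import cluster_sums, gamma_marginal_terms
from .cohort import Cohort, DesignMatrix, build_design

logger = logging.getLogger(__name__)

PH_FAMILIES = ("exponential", "weibull")
AFT_FAMILIES = ("exponential", "weibull", "loglogistic", "lognormal", "gamma")
GH_NODES = 15


class FamilyError(ValueError):
    pass


def _check_family(family: str, parameterization: str) -> None:
    if parameterization == "PH":
        if family not in PH_FAMILIES:
            raise FamilyError(
                f"{family} has no PH parameterisation (PH: {PH_FAMILIES})"
            )
    elif parameterization == "AFT":
        if family not in AFT_FAMILIES:
            raise FamilyError(f"unknown AFT family {family!r}")
    else:
        raise FamilyError(f"parameterization must be 'PH' or 'AFT', got {parameterization!r}")


def n_ancillary(family: str, parameterization: str) -> int:
    """Number of baseline/shape parameters (before covariates and frailty)."""
    if parameterization == "PH":
        return 1 if family == "exponential" else 2         # log lam (, log gam)
    return {"exponential": 1, "weibull": 2, "loglogistic": 2,
            "lognormal": 2, "gamma": 3}[family]            # mu (, log sigma)(, log a)


# ---------------------------------------------------------------------------
# per-record log f and log S
# ---------------------------------------------------------------------------

def _logf_logS(family, parameterization, anc, lin, t):
    """Vectorised log density and log survival at times ``t``.

    ``lin`` is the covariate linear predictor x*beta (PH: on the log-hazard
    scale; AFT: added to the location of log time).
    """
    logt = np.log(t)
    if parameterization == "PH":
        if family == "exponential":
            (loglam,) = anc
            logh = loglam + lin
            H = np.exp(loglam + lin) * t
        else:  # weibull
            loglam, loggam = anc
            gam = np.exp(loggam)
            logh = loglam + loggam + (gam - 1.0) * logt + lin
            H = np.exp(loglam + gam * logt + lin)
        return logh - H, -H

    # AFT: location mu + x beta on log time
    if family == "exponential":
        return _exp_aft_fix(anc, lin, t)
    if family == "weibull":
        mu, logsig = anc
        sig = np.exp(logsig)
        z = (logt - (mu + lin)) / sig
        logf = -logsig - logt + z - np.exp(z)
        return logf, -np.exp(z)
    if family == "lognormal":
        mu, logsig = anc
        sig = np.exp(logsig)
        z = (logt - (mu + lin)) / sig
        return norm.logpdf(z) - logsig - logt, norm.logsf(z)
    if family == "loglogistic":
        mu, logsig = anc
        sig = np.exp(logsig)
        z = (logt - (mu + lin)) / sig
        return z - logsig - logt - 2.0 * np.logaddexp(0.0, z), -np.logaddexp(0.0, z)
    if family == "gamma":
        # generalized gamma (positive-shape branch): u = (t/e^loc)^c ~ Gamma(a)
        mu, logsig, loga = anc
        a = np.exp(loga)
        c = 1.0 / np.exp(logsig)
        z = c * (logt - (mu + lin))
        u = np.exp(np.clip(z, -700, 700))
        logf = np.log(c) + a * z - u - logt - gammaln(a)
        S = gammaincc(a, u)
        logS = np.log(np.clip(S, 1e-300, None))
        return logf, logS
    raise FamilyError(family)


def _exp_aft_fix(anc, lin, t):
    """Exponential AFT closed form (kept separate for clarity)."""
    (mu,) = anc
    loc = mu + lin
    lam = np.exp(-loc)
    return np.log(lam) - lam * t, -lam * t


# ---------------------------------------------------------------------------
# log-likelihood
# ---------------------------------------------------------------------------

def _unpack(params, family, parameterization, p, frailty_kind):
    na = n_ancillary(family, parameterization)
    anc = tuple(params[:na])
    beta = np.asarray(params[na:na + p], float)
    extra = params[na + p:]
    return anc, beta, extra


def loglik_parametric(params, cohort: Cohort, family: str,
                      parameterization: str = "PH",
                      frailty_kind: str | None = None,
                      design: DesignMatrix | None = None) -> float:
    """Censored-data (marginal) log-likelihood at the packed parameter vector.

    Packing: ancillary parameters, then covariate coefficients, then (for a
    frailty model) the log of the frailty variance theta / random-intercept
    variance.
    """
    _check_family(family, parameterization)
    design = design or build_design(cohort)
    X = design.values
    t = cohort.exit
    d = cohort.event.astype(float)
    entry = cohort.entry
    if np.any(t <= 0):
        raise ValueError("all exit times must be positive")
    anc, beta, extra = _unpack(params, family, parameterization, X.shape[1], frailty_kind)
    lin = X @ beta

    if frailty_kind is None:
        if family == "exponential" and parameterization == "AFT":
            logf, logS = _exp_aft_fix(anc, lin, t)
        else:
            logf, logS = _logf_logS(family, parameterization, anc, lin, t)
        ll = float(np.sum(d * logf + (1 - d) * logS))
        if np.any(entry > 0):
            pos = entry > 0
            _, logS0 = _logf_logS(family, parameterization, anc, lin[pos], entry[pos])
            ll -= float(np.sum(logS0))
        return ll

    if np.any(entry > 0):
        raise ValueError("delayed entry is not supported with frailty")
    cluster = cohort.cluster_codes
    G = cohort.n_clusters
    theta = float(np.exp(extra[0]))

    if frailty_kind == "gamma":
        if parameterization != "PH":
            raise FamilyError("gamma (hazard) frailty requires a PH family")
        logf, logS = _logf_logS(family, parameterization, anc, lin, t)
        logh = logf - logS
        H = -logS
        D = cluster_sums(d, cluster, G)
        A = cluster_sums(H, cluster, G)
        return float(np.sum(d * logh)) + gamma_marginal_terms(theta, D, A)

    if frailty_kind == "normal":
        if parameterization != "AFT":
            raise FamilyError("normal random intercept requires an AFT family")
        tau = np.sqrt(theta)
        nodes, weights = np.polynomial.hermite.hermgauss(GH_NODES)
        # per-node conditional log-likelihood per record, then per cluster
        contrib = np.empty((GH_NODES, G))
        for k, u in enumerate(np.sqrt(2.0) * tau * nodes):
            if family == "exponential":
                logf, logS = _exp_aft_fix(anc, lin + u, t)
            else:
                logf, logS = _logf_logS(family, parameterization, anc, lin + u, t)
            rec = d * logf + (1 - d) * logS
            contrib[k] = cluster_sums(rec, cluster, G)
        logw = np.log(weights / np.sqrt(np.pi))
        from scipy.special import logsumexp
        return float(np.sum(logsumexp(contrib + logw[:, None], axis=0)))

    raise FamilyError(f"unknown frailty kind {frailty_kind!r}")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class ParametricFit:
    family: str
    parameterization: str
    beta: np.ndarray
    ancillary: dict
    frailty_kind: str | None
    theta: float
    loglik: float
    loglik_null: float
    covariance: np.ndarray
    columns: tuple[str, ...]
    n_events: int
    warnings_: list[str] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        return (
            n_ancillary(self.family, self.parameterization)
            + len(self.beta)
            + (1 if self.frailty_kind else 0)
        )

    def summary(self):
        import pandas as pd

        na = n_ancillary(self.family, self.parameterization)
        se = np.sqrt(np.clip(np.diag(self.covariance), 0, None))[na:na + len(self.beta)]
        z = np.divide(self.beta, se, out=np.zeros_like(self.beta), where=se > 0)
        sign = -1.0 if self.parameterization == "AFT" else 1.0
        return pd.DataFrame(
            {
                "term": self.columns,
                "coef": self.beta,
                # PH: exp(beta) is a hazard ratio; AFT: exp(beta) is a time ratio
                "ratio": np.exp(self.beta),
                "ratio_low": np.exp(self.beta - 1.96 * se),
                "ratio_high": np.exp(self.beta + 1.96 * se),
                "p": 2 * norm.sf(np.abs(z)),
            }
        )


def _start_values(cohort, family, parameterization, p, frailty_kind):
    rate = max(cohort.n_events, 1) / cohort.person_time
    mean_logt = float(np.mean(np.log(cohort.exit)))
    if parameterization == "PH":
        anc = [np.log(rate)] if family == "exponential" else [np.log(rate), 0.0]
    else:
        base = {"exponential": [mean_logt],
                "weibull": [mean_logt, 0.0],
                "loglogistic": [mean_logt, 0.0],
                "lognormal": [mean_logt, 0.0],
                "gamma": [mean_logt, 0.0, 0.0]}
        anc = base[family]
    x0 = anc + [0.0] * p
    if frailty_kind:
        x0 = x0 + [np.log(0.25)]
    return np.array(x0)


def _numeric_hessian(fun, x, h=1e-5):
    n = len(x)
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            hi = h * max(1.0, abs(x[i]))
            hj = h * max(1.0, abs(x[j]))
            if i == j:
                e = np.zeros(n); e[i] = hi
                H[i, i] = (fun(x + e) - 2 * f0 + fun(x - e)) / hi ** 2
            else:
                ei = np.zeros(n); ei[i] = hi
                ej = np.zeros(n); ej[j] = hj
                H[i, j] = H[j, i] = (
                    fun(x + ei + ej) - fun(x + ei - ej)
                    - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4 * hi * hj)
    return H


def fit_parametric(cohort: Cohort, family: str, parameterization: str = "PH",
                   frailty_kind: str | None = None,
                   design: DesignMatrix | None = None,
                   compute_null: bool = True,
                   compute_covariance: bool = True) -> ParametricFit:
    """Maximum (marginal) likelihood fit of one parametric family.

    Ancillary parameters are estimated on the log scale for positivity.
    ``frailty_kind``: None, ``'gamma'`` (PH families) or ``'normal'`` (AFT).
    """
    _check_family(family, parameterization)
    if frailty_kind and cohort.n_clusters < 2:
        raise ValueError("frailty model requires at least 2 clusters")
    design = design or build_design(cohort)
    p = design.values.shape[1]

    def negll(x):
        try:
            val = loglik_parametric(x, cohort, family, parameterization,
                                    frailty_kind, design)
        except (FloatingPointError, OverflowError):
            return 1e12
        return -val if np.isfinite(val) else 1e12

    x0 = _start_values(cohort, family, parameterization, p, frailty_kind)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        res = minimize(negll, x0, method="L-BFGS-B",
                       options={"maxiter": 2000, "ftol": 1e-12})
        # polish with a derivative-free pass in case finite differences stall
        res2 = minimize(negll, res.x, method="Nelder-Mead",
                        options={"maxiter": 400 * len(x0), "xatol": 1e-8,
                                 "fatol": 1e-10})
    best = res2 if res2.fun < res.fun else res
    if not (res.success or res2.success):
        raise RuntimeError(
            f"{family}/{parameterization} fit did not converge: {best.message}"
        )
    x = best.x
    ll = -best.fun
    anc, beta, extra = _unpack(x, family, parameterization, p, frailty_kind)
    na = n_ancillary(family, parameterization)
    cov = np.full((len(x), len(x)), np.nan)
    if compute_covariance:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            H = _numeric_hessian(negll, x)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            logger.warning("singular Hessian for %s/%s", family, parameterization)

    ll_null = np.nan
    if compute_null:
        if p == 0:
            ll_null = ll
        else:
            null_design = DesignMatrix(np.zeros((len(cohort), 0)), (), ())
            null = fit_parametric(cohort, family, parameterization, frailty_kind,
                                  design=null_design, compute_null=False,
                                  compute_covariance=False)
            ll_null = null.loglik

    anc_names = {
        ("PH", 1): ["log_lambda"], ("PH", 2): ["log_lambda", "log_gamma"],
        ("AFT", 1): ["mu"], ("AFT", 2): ["mu", "log_sigma"],
        ("AFT", 3): ["mu", "log_sigma", "log_a"],
    }[(parameterization, na)]
    return ParametricFit(
        family=family,
        parameterization=parameterization,
        beta=beta,
        ancillary=dict(zip(anc_names, anc)),
        frailty_kind=frailty_kind,
        theta=float(np.exp(extra[0])) if frailty_kind else 0.0,
        loglik=float(ll),
        loglik_null=float(ll_null),
        covariance=cov,
        columns=design.columns,
        n_events=cohort.n_events,
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_parametric(fit: ParametricFit, covariates, times,
                       marginal: bool = False):
    """Hazard, cumulative hazard and survival curves for one covariate pattern.

    ``covariates`` is either a dummy vector matching the design columns or a
    mapping category -> level (reference levels may be omitted).  With
    ``marginal=True`` and a gamma frailty, population-averaged curves
    ``S_m = (1 + theta H)^(-1/theta)`` are returned.
    """
    times = np.asarray(times, float)
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    x = _pattern_vector(covariates, fit.columns)
    lin = float(x @ fit.beta)
    anc = tuple(fit.ancillary.values())
    if fit.family == "exponential" and fit.parameterization == "AFT":
        logf, logS = _exp_aft_fix(anc, lin, times)
    else:
        logf, logS = _logf_logS(fit.family, fit.parameterization, anc, lin, times)
    H = -logS
    S = np.exp(logS)
    h = np.exp(logf - logS)
    if marginal and fit.frailty_kind == "gamma" and fit.theta > 0:
        th = fit.theta
        S = (1.0 + th * H) ** (-1.0 / th)
        h = h / (1.0 + th * H)
        H = np.log1p(th * H) / th
    return {"time": times, "hazard": h, "cumhaz": H, "survival": S}


def _pattern_vector(covariates, columns) -> np.ndarray:
    if isinstance(covariates, dict):
        x = np.zeros(len(columns))
        for cat, lev in covariates.items():
            label = f"{cat}={lev}"
            if label in columns:
                x[columns.index(label)] = 1.0
            else:
                ok = any(c.startswith(f"{cat}=") for c in columns)
                if not ok:
                    raise ValueError(f"unknown covariate category {cat!r}")
                # reference level: contributes no column
        return x
    x = np.asarray(covariates, float)
    if x.shape != (len(columns),):
        raise ValueError("covariate vector length mismatch")
    return x
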