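"""Closed-form marginal likelihood for shared gamma frailty.

For a cluster ``g`` with event indicators ``d_i``, conditional hazards
``h_i`` and cumulative hazards ``H_i`` (covariates included), integrating a
multiplicative mean-1, variance-theta gamma frailty out of the conditional
likelihood gives the cluster contribution

    prod_i h_i^{d_i} * theta^{D_g} * Gamma(1/theta + D_g) / Gamma(1/theta)
        / (1 + theta * sum_i H_i)^{1/theta + D_g}

with ``D_g = sum_i d_i``.  Because the event counts are integers, the gamma
ratio times ``theta^D`` telescopes to ``prod_{j<D} (1 + j*theta)`` — this
form is used throughout since it stays exact as ``theta -> 0`` where the
``lgamma`` difference suffers catastrophic cancellation.

The gradient of the marginal log-likelihood w.r.t. any parameter ``p`` of
the conditional model is ``sum_i d_i dlog h_i/dp - sum_i c_g(i) dH_i/dp``
with per-cluster weight ``c_g = (1 + theta D_g) / (1 + theta A_g)`` and
``A_g = sum_i H_i``.
"""

from __future__ import annotations

import numpy as np


def cluster_sums(values: np.ndarray, cluster: np.ndarray, G: int) -> np.ndarray:
    return np.bincount(cluster, weights=values, minlength=G)


def _log_rising(theta: float, D: np.ndarray) -> float:
    """sum over clusters of sum_{j=0}^{D_g-1} log(1 + j*theta)."""
    out = 0.0
    for j in range(1, int(np.max(D)) if D.size else 0):
        out += float(np.log1p(j * theta) * np.count_nonzero(D > j))
    return out


def gamma_marginal_terms(theta: float, D: np.ndarray, A: np.ndarray) -> float:
    """Sum over clusters of the frailty terms (excludes sum d*log h)."""
    a = 1.0 / theta
    return _log_rising(theta, D) - float(np.sum((a + D) * np.log1p(theta * A)))


def gamma_marginal_weights(theta: float, D: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Per-cluster weight c_g multiplying dH contributions in the gradient."""
    return (1.0 + theta * D) / (1.0 + theta * A)


def gamma_marginal_dlogtheta(theta: float, D: np.ndarray, A: np.ndarray) -> float:
    """d/d(log theta) of :func:`gamma_marginal_terms` at fixed D, A."""
    a = 1.0 / theta
    dtheta = 0.0
    for j in range(1, int(np.max(D)) if D.size else 0):
        dtheta += float(j / (1.0 + j * theta) * np.count_nonzero(D > j))
    dtheta += float(
        np.sum((a ** 2) * np.log1p(theta * A) - (a + D) * A / (1.0 + theta * A))
    )
    return dtheta * theta
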