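"""Negative-binomial regression of MOTU counts on sampling effort.

Tree-based delimitation tends to oversplit well-sampled species, so the
number of MOTUs recovered per species grows with the number of sequenced
specimens.  That relationship is modelled as an NB2 generalized linear model
with a log link:

    y_i ~ NegBin(mu_i, theta),   mu_i = exp(beta0 + beta1 * x_i),
    Var(y_i) = mu_i + mu_i^2 / theta,

where x_i is the species' sample size and theta > 0 the dispersion (size)
parameter; theta -> infinity recovers the Poisson model.

Fitting alternates iteratively reweighted least squares for beta (Fisher
scoring with step halving, so the log-likelihood never decreases) with a
golden-section profile maximisation of the likelihood over log(theta).
Standard errors come from the inverse observed information at the optimum;
the slope is tested with a Wald z statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import norm

from .io_model import BarcodeAuditError

__all__ = ["CountModelFit", "fit_nb_glm", "predict", "nb2_loglik", "simulate_counts"]

logger = logging.getLogger(__name__)

_THETA_LOG_BOUNDS = (np.log(1e-3), np.log(1e8))
_REL_TOL = 1e-8
_MAX_OUTER = 100


@dataclass
class CountModelFit:
    """Fitted NB2 GLM (log link) of counts on a single covariate."""

    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    theta: float
    n_obs: int
    z_slope: float
    p_slope: float
    loglik: float
    converged: bool
    n_iter: int
    #: outer-iteration log-likelihood trace; non-decreasing by construction
    ll_trace: list[float] = field(default_factory=list)


def nb2_loglik(beta: np.ndarray, theta: float, x: np.ndarray, y: np.ndarray) -> float:
    """NB2 log-likelihood at coefficients ``beta`` and dispersion ``theta``."""
    mu = np.exp(beta[0] + beta[1] * x)
    return float(
        np.sum(
            gammaln(y + theta)
            - gammaln(theta)
            - gammaln(y + 1.0)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def _irls_step(
    beta: np.ndarray, theta: float, x: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """One Fisher-scoring step for beta at fixed theta, with step halving."""
    X = np.column_stack([np.ones_like(x), x])
    ll0 = nb2_loglik(beta, theta, x, y)
    mu = np.exp(X @ beta)
    w = mu / (1.0 + mu / theta)  # Fisher weights for NB2 log link
    score = X.T @ ((y - mu) * theta / (theta + mu))
    info = X.T @ (w[:, None] * X)
    try:
        step = np.linalg.solve(info, score)
    except np.linalg.LinAlgError as exc:
        raise BarcodeAuditError("rank-deficient design (constant covariate)") from exc
    scale = 1.0
    for _ in range(30):
        cand = beta + scale * step
        if nb2_loglik(cand, theta, x, y) >= ll0 - 1e-12:
            return cand
        scale /= 2.0
    return beta


def _profile_theta(beta: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    res = minimize_scalar(
        lambda lt: -nb2_loglik(beta, float(np.exp(lt)), x, y),
        bounds=_THETA_LOG_BOUNDS,
        method="bounded",
        options={"xatol": 1e-10},
    )
    # Equi-/under-dispersed data leave the profile flat towards theta ->
    # infinity; pin such fits to the upper bound (the Poisson limit) so the
    # outer loop sees a stable theta instead of plateau jitter.
    theta_hi = float(np.exp(_THETA_LOG_BOUNDS[1]))
    ll_opt = -res.fun
    ll_hi = nb2_loglik(beta, theta_hi, x, y)
    if ll_hi >= ll_opt - 1e-10 * (abs(ll_opt) + 1.0):
        return theta_hi
    return float(np.exp(res.x))


def fit_nb_glm(x, y) -> CountModelFit:
    """Fit the NB2 GLM of counts ``y`` on covariate ``x``.

    Observations should already be restricted to species with more than one
    specimen when modelling MOTU counts vs sample size.  Raises on a
    rank-deficient design (all ``x`` identical); non-convergence within the
    iteration budget is flagged on the fit, not raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise BarcodeAuditError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise BarcodeAuditError("need at least 3 observations")
    if np.any(y < 0) or np.any(y != np.rint(y)):
        raise BarcodeAuditError("y must be non-negative integer counts")
    if np.allclose(x, x[0]):
        raise BarcodeAuditError("rank-deficient design: all x identical")

    # init from a log-linear least-squares fit
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.lstsq(X, np.log(y + 0.5), rcond=None)[0]
    theta = 1.0
    ll = nb2_loglik(beta, theta, x, y)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, _MAX_OUTER + 1):
        beta = _irls_step(beta, theta, x, y)
        theta = _profile_theta(beta, x, y)
        ll_new = nb2_loglik(beta, theta, x, y)
        trace.append(ll_new)
        if abs(ll_new - ll) <= _REL_TOL * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged:
        logger.warning("NB GLM did not converge in %d iterations", _MAX_OUTER)

    mu = np.exp(X @ beta)
    # observed information: -d2l/dbeta2 = X' diag(theta*mu*(theta+y)/(theta+mu)^2) X
    w_obs = theta * mu * (theta + y) / (theta + mu) ** 2
    info = X.T @ (w_obs[:, None] * X)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = float(beta[1] / se[1]) if se[1] > 0 else float("nan")
    p = float(2.0 * norm.sf(abs(z)))
    return CountModelFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        se_beta0=float(se[0]),
        se_beta1=float(se[1]),
        theta=theta,
        n_obs=len(x),
        z_slope=z,
        p_slope=p,
        loglik=float(ll),
        converged=converged,
        n_iter=it,
        ll_trace=trace,
    )


def predict(fit: CountModelFit, x) -> np.ndarray | float:
    """Expected count ``exp(beta0 + beta1 * x)``."""
    x = np.asarray(x, dtype=float)
    out = np.exp(fit.beta0 + fit.beta1 * x)
    return float(out) if out.ndim == 0 else out


def simulate_counts(
    beta0: float, beta1: float, theta: float, x, rng: np.random.Generator
) -> np.ndarray:
    """Draw NB2 counts at covariate values ``x`` (for calibration studies)."""
    x = np.asarray(x, dtype=float)
    mu = np.exp(beta0 + beta1 * x)
    # NB2 as a gamma-Poisson mixture
    lam = rng.gamma(shape=theta, scale=mu / theta)
    return rng.poisson(lam)
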