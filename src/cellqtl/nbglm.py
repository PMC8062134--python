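"""Negative-binomial (gamma-Poisson) GLM with log link, fit by IRLS.

UMI counts are modeled as Y ~ NB(mu, theta) with E[Y] = mu,
Var(Y) = mu + mu^2 / theta and log mu = X beta. The log-likelihood is

    l(beta, theta) = sum_n [ lgamma(y_n + theta) - lgamma(theta)
                             - lgamma(y_n + 1) + theta log theta
                             + y_n log mu_n - (y_n + theta) log(mu_n + theta) ]

beta is estimated by iteratively reweighted least squares with step
halving as a safeguard; when theta is not supplied it is profiled out by
alternating a one-dimensional likelihood maximization over log theta with
the IRLS updates. For the eQTL scans theta is estimated once per
transcript (on the full cis model) and reused with theta held fixed,
which keeps genome-wide scans tractable and is conservative: unmodeled
effects inflate the overdispersion estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2

_ETA_MAX = 30.0  # linear-predictor clamp; exp(30) ~ 1e13 counts


@dataclass
class NBFit:
    """Result of a negative-binomial GLM fit."""

    beta: np.ndarray
    theta: float
    loglik: float
    converged: bool
    flagged: bool = False  # linear predictor hit the overflow clamp
    n_iter: int = 0


def nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """NB log-likelihood at mean ``mu`` and overdispersion ``theta``."""
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    return float(
        np.sum(
            gammaln(y + theta)
            - gammaln(theta)
            - gammaln(y + 1.0)
            + theta * np.log(theta)
            + y * np.log(mu)
            - (y + theta) * np.log(mu + theta)
        )
    )


def _irls(y, X, theta, beta0=None, max_iter=50, tol=1e-8):
    """IRLS for beta with theta fixed; returns (beta, mu, ll, converged, flagged)."""
    n = y.shape[0]
    if beta0 is None:
        mu = np.maximum((y + y.mean()) / 2.0, 0.1)
        eta = np.log(mu)
        beta = None
    else:
        beta = beta0.copy()
        eta = np.clip(X @ beta, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
    ll = -np.inf if beta is None else nb_loglik(y, mu, theta)
    flagged = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu * theta / (theta + mu)
        z = eta + (y - mu) / mu
        wx = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ wx, wx.T @ z)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "singular weighted design in IRLS (collinear covariates?)"
            ) from err
        eta_new = X @ beta_new
        if np.any(np.abs(eta_new) > _ETA_MAX):
            flagged = True
            eta_new = np.clip(eta_new, -_ETA_MAX, _ETA_MAX)
        mu_new = np.exp(eta_new)
        ll_new = nb_loglik(y, mu_new, theta)
        if beta is not None and ll_new < ll:
            # step halving toward the previous estimate
            for _ in range(20):
                beta_new = 0.5 * (beta_new + beta)
                eta_new = np.clip(X @ beta_new, -_ETA_MAX, _ETA_MAX)
                mu_new = np.exp(eta_new)
                ll_new = nb_loglik(y, mu_new, theta)
                if ll_new >= ll:
                    break
            if ll_new < ll:  # no improving step: accept previous optimum
                converged = True
                break
        if beta is not None and abs(ll_new - ll) <= tol * (abs(ll) + 1.0):
            beta, mu, eta, ll = beta_new, mu_new, eta_new, ll_new
            converged = True
            break
        beta, mu, eta, ll = beta_new, mu_new, eta_new, ll_new
    return beta, mu, ll, converged, flagged, it


def _mle_theta(y, mu, bracket=(-7.0, 12.0)):
    """Maximize the NB log-likelihood over log(theta) with mu fixed."""
    res = minimize_scalar(
        lambda t: -nb_loglik(y, mu, np.exp(t)),
        bounds=bracket,
        method="bounded",
        options={"xatol": 1e-7},
    )
    return float(np.exp(res.x))


def fit_nb_glm(
    y,
    X,
    theta: float | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> NBFit:
    """Fit the NB GLM ``log mu = X beta``.

    Parameters
    ----------
    y
        Non-negative integer counts, length n.
    X
        Dense model matrix (n, p) of full column rank, n > p.
    theta
        If given, held fixed; otherwise estimated by maximum likelihood,
        alternating with the IRLS beta updates.
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) matching len(y)")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than coefficients ({p})")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("model matrix is rank deficient")

    if theta is not None:
        if theta <= 0:
            raise ValueError("theta must be positive")
        beta, mu, ll, conv, flagged, it = _irls(y, X, theta, None, max_iter, tol)
        return NBFit(beta, float(theta), ll, conv, flagged, it)

    # alternate beta | theta and theta | mu
    th = 1.0
    beta = None
    ll_prev = -np.inf
    conv = False
    flagged = False
    total_it = 0
    for _ in range(25):
        beta, mu, ll, conv_b, flg, it = _irls(y, X, th, beta, max_iter, tol)
        total_it += it
        flagged = flagged or flg
        th = _mle_theta(y, mu)
        ll = nb_loglik(y, mu, th)
        if abs(ll - ll_prev) <= 1e-6 * (abs(ll) + 1.0):
            conv = conv_b
            break
        ll_prev = ll
    # final beta polish at the estimated theta
    beta, mu, ll, conv_b, flg, it = _irls(y, X, th, beta, max_iter, tol)
    return NBFit(beta, th, ll, conv and conv_b, flagged or flg, total_it + it)


def lrt_lod(l_full: float, l_reduced: float, slack: float = 1e-6):
    """Likelihood-ratio statistic, LOD score and chi2(1) p-value.

    LRT = -2 (l_reduced - l_full); LOD = LRT / (2 ln 10). A slightly
    negative LRT within ``slack`` (numerical noise from nested fits) is
    truncated to zero; beyond slack it is an error.
    """
    lrt = -2.0 * (l_reduced - l_full)
    if lrt < -slack:
        raise ValueError(
            f"reduced model out-fits full model (LRT={lrt:.3g}); refit required"
        )
    lrt = max(lrt, 0.0)
    lod = lrt / (2.0 * np.log(10.0))
    p = float(chi2.sf(lrt, df=1))
    return lrt, lod, p
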