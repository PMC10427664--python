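"""Maximum-likelihood logistic regression with a family random intercept.

A deterministic analogue of a hierarchical exploitation-on-traits model:

    exploited ~ traits + (1 | family),   u_family ~ N(0, sigma^2)

The marginal likelihood integrates the family intercepts out with adaptive
Gauss-Hermite quadrature centred at each family's conditional mode (found by
a vectorized Newton inner loop); one quadrature node gives the Laplace
approximation. The outer optimization over (beta, log sigma) is L-BFGS-B,
started from an unpenalized logistic fit, so the whole fit is deterministic
given the data.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, log_expit

__all__ = ["fit_logistic_mixed", "fit_logistic_plain"]

_MAX_NEWTON = 60
_NEWTON_TOL = 1e-11


def fit_logistic_plain(
    X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> np.ndarray:
    """Plain logistic regression via Newton-Raphson (IRLS); returns beta."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        H = X.T @ (X * w[:, None]) + 1e-10 * np.eye(p)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _family_modes(
    eta: np.ndarray,
    y: np.ndarray,
    fidx: np.ndarray,
    n_fam: int,
    sigma2: float,
    u0: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional modes u* and curvatures -g'' per family (vectorized Newton)."""
    u = u0.copy()
    for _ in range(_MAX_NEWTON):
        mu = expit(eta + u[fidx])
        score = np.bincount(fidx, weights=y - mu, minlength=n_fam) - u / sigma2
        info = np.bincount(fidx, weights=mu * (1 - mu), minlength=n_fam) + 1.0 / sigma2
        step = score / info
        u += step
        if np.max(np.abs(step)) < _NEWTON_TOL:
            break
    mu = expit(eta + u[fidx])
    curv = np.bincount(fidx, weights=mu * (1 - mu), minlength=n_fam) + 1.0 / sigma2
    return u, curv


def _marginal_nll(
    params: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    fidx: np.ndarray,
    n_fam: int,
    gh_x: np.ndarray,
    gh_logw: np.ndarray,
    u_cache: np.ndarray,
) -> float:
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    sigma2 = sigma * sigma
    eta = X @ beta
    u, curv = _family_modes(eta, y, fidx, n_fam, sigma2, u_cache)
    u_cache[:] = u  # warm start for the next outer evaluation
    s = 1.0 / np.sqrt(curv)  # per-family quadrature scale

    # g_f(u) = sum_i [y log mu + (1-y) log(1-mu)] - u^2 / (2 sigma^2)
    nodes = u[:, None] + np.sqrt(2.0) * s[:, None] * gh_x[None, :]  # (F, Q)
    eta_nodes = eta[:, None] + nodes[fidx]  # (n, Q)
    ll_obs = np.where(y[:, None] > 0, log_expit(eta_nodes), log_expit(-eta_nodes))
    g = np.zeros((n_fam, len(gh_x)))
    np.add.at(g, fidx, ll_obs)
    g -= nodes**2 / (2.0 * sigma2)
    # log integral via Gauss-Hermite: log( sqrt(2) s sum_k w_k e^{g_k + x_k^2} )
    a = g + gh_logw[None, :] + gh_x[None, :] ** 2
    amax = a.max(axis=1)
    log_int = amax + np.log(np.exp(a - amax[:, None]).sum(axis=1))
    log_int += 0.5 * np.log(2.0) + np.log(s)
    ll = float(np.sum(log_int - 0.5 * np.log(2 * np.pi * sigma2)))
    return -ll


def fit_logistic_mixed(
    X: np.ndarray,
    y: np.ndarray,
    family_index: np.ndarray,
    n_quad: int = 9,
    max_outer: int = 400,
) -> dict:
    """Fit the random-intercept logistic model by marginal maximum likelihood.

    ``X`` must include an intercept column; ``family_index`` maps each row to
    a 0-based family id. Returns a dict with ``beta``, ``sigma``, ``loglik``,
    ``converged`` and a complete-separation flag.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    fidx = np.asarray(family_index, dtype=int)
    n, p = X.shape
    n_fam = int(fidx.max()) + 1
    if n <= p:
        raise ValueError("more parameters than observations")
    if n_fam < 2:
        raise ValueError("at least 2 families required")
    if y.min() == y.max():
        raise ValueError("outcome must include both classes")
    gh_x, gh_w = hermgauss(n_quad)
    gh_logw = np.log(gh_w)
    u_cache = np.zeros(n_fam)

    beta0 = fit_logistic_plain(X, y)
    x0 = np.concatenate([beta0, [np.log(0.5)]])
    res = optimize.minimize(
        _marginal_nll,
        x0,
        args=(X, y, fidx, n_fam, gh_x, gh_logw, u_cache),
        method="L-BFGS-B",
        options={"maxiter": max_outer, "ftol": 1e-12, "gtol": 1e-8},
    )
    beta = res.x[:-1]
    sigma = float(np.exp(res.x[-1]))
    separation = bool(np.max(np.abs(beta)) > 15.0)
    return {
        "beta": beta,
        "sigma": sigma,
        "loglik": -float(res.fun),
        "converged": bool(res.success) and not separation,
        "separation_flag": separation,
        "n_obs": n,
        "n_families": n_fam,
    }
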