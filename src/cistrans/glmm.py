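"""Random-intercept logistic regression by adaptive Gauss-Hermite quadrature.

Maximum-likelihood logistic mixed model with a single grouping factor
(donor).  The per-group marginal likelihood integral over the random
intercept is computed by adaptive GH quadrature: each group's integrand is
re-centered at its posterior mode (found by a vectorized Newton iteration)
and scaled by the local curvature before applying the quadrature rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special


def _log_expit_terms(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-observation Bernoulli log-likelihood log p(y | logit = eta)."""
    return y * eta - np.logaddexp(0.0, eta)


class _GroupData:
    def __init__(self, X: np.ndarray, y: np.ndarray, group_idx: np.ndarray):
        self.X = X
        self.y = y
        self.group_idx = group_idx
        self.n_groups = int(group_idx.max()) + 1


def _marginal_loglik(
    params: np.ndarray, data: _GroupData, nodes: np.ndarray, weights: np.ndarray
) -> float:
    beta = params[:-1]
    sigma = np.exp(params[-1])
    xb = data.X @ beta
    G = data.n_groups
    # find posterior mode of u_g for each group by Newton iteration
    u = np.zeros(G)
    for _ in range(50):
        eta = xb + sigma * u[data.group_idx]
        mu = special.expit(eta)
        grad_obs = (data.y - mu) * sigma
        grad = np.bincount(data.group_idx, grad_obs, minlength=G) - u
        hess_obs = mu * (1 - mu) * sigma**2
        hess = -np.bincount(data.group_idx, hess_obs, minlength=G) - 1.0
        step = grad / hess
        u = u - step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = xb + sigma * u[data.group_idx]
    mu = special.expit(eta)
    curv = np.bincount(data.group_idx, mu * (1 - mu) * sigma**2, minlength=G) + 1.0
    tau = 1.0 / np.sqrt(curv)
    # adaptive GH: integral = sqrt(2) tau sum_k w_k exp(x_k^2) h(u* + sqrt(2) tau x_k)
    pts = u[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]
    logh = np.empty((G, nodes.size))
    for k in range(nodes.size):
        eta_k = xb + sigma * pts[data.group_idx, k]
        terms = _log_expit_terms(eta_k, data.y)
        logh[:, k] = np.bincount(data.group_idx, terms, minlength=G) - 0.5 * pts[:, k] ** 2
    log_integrand = logh + nodes[None, :] ** 2 + np.log(weights)[None, :]
    mx = log_integrand.max(axis=1)
    log_int = mx + np.log(np.exp(log_integrand - mx[:, None]).sum(axis=1))
    log_int += 0.5 * np.log(2.0) + np.log(tau) - 0.5 * np.log(2.0 * np.pi)
    return float(log_int.sum())


@dataclass
class LinearMixedFit:
    params: np.ndarray
    sigma: float  # residual SD
    tau: float  # random-intercept SD
    loglik: float


def fit_linear_mixed(X: np.ndarray, y: np.ndarray, groups: np.ndarray) -> LinearMixedFit:
    """ML fit of y = X beta + u_group + e by profiled likelihood.

    With psi = tau^2/sigma^2, beta and sigma^2 have closed GLS forms, leaving
    a 1-D maximization over psi (Woodbury identity per group, so cost is
    linear in n).  Robust on boundary cases: psi = 0 reduces exactly to OLS.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _, gidx = np.unique(groups, return_inverse=True)
    G = int(gidx.max()) + 1
    n = y.size
    ng = np.bincount(gidx, minlength=G).astype(float)
    Sx = np.stack([np.bincount(gidx, X[:, j], minlength=G) for j in range(X.shape[1])], axis=1)
    Sy = np.bincount(gidx, y, minlength=G)
    XtX = X.T @ X
    Xty = X.T @ y

    def profile(psi: float):
        c = psi / (1.0 + psi * ng)  # per-group shrinkage weight
        A = XtX - (Sx * c[:, None]).T @ Sx
        b = Xty - Sx.T @ (c * Sy)
        beta = np.linalg.solve(A, b)
        r = y - X @ beta
        Sr = np.bincount(gidx, r, minlength=G)
        rss = r @ r - c @ Sr**2
        sigma2 = rss / n
        ll = -0.5 * n * np.log(2 * np.pi * sigma2) - 0.5 * np.sum(np.log1p(psi * ng)) - 0.5 * n
        return ll, beta, sigma2

    def neg(t: float) -> float:
        return -profile(np.exp(t) - 1e-8)[0]

    # bracket on a log grid, then refine
    grid = np.concatenate([[-18.0], np.linspace(-8, 4, 25)])
    vals = [neg(t) for t in grid]
    t0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(neg, bounds=(t0 - 1.0, t0 + 1.0), method="bounded")
    psi = max(np.exp(res.x) - 1e-8, 0.0)
    ll0, beta0, s20 = profile(0.0)
    ll, beta, sigma2 = profile(psi)
    if ll0 >= ll:  # boundary solution: plain OLS
        psi, ll, beta, sigma2 = 0.0, ll0, beta0, s20
    return LinearMixedFit(
        params=beta,
        sigma=float(np.sqrt(sigma2)),
        tau=float(np.sqrt(psi * sigma2)),
        loglik=float(ll),
    )


@dataclass
class JointHurdleFit:
    """Two-part hurdle with one shared donor random intercept.

    logit P(detected) = X beta_d + a u_g;  value | detected ~
    N(X beta_c + b u_g, sigma_e^2);  u_g ~ N(0, 1).  The shared u makes the
    two parts' donor contributions explicitly dependent, so the 2-df LRT on
    diagnosis (dropped from both parts at once) is a true likelihood ratio.
    """

    beta_discrete: np.ndarray
    beta_continuous: np.ndarray
    loading_discrete: float  # a >= 0
    loading_continuous: float  # b, free sign
    sigma_resid: float
    loglik: float
    converged: bool


def _joint_loglik(
    params: np.ndarray,
    Xd: np.ndarray,
    y_det: np.ndarray,
    gidx: np.ndarray,
    Xc: np.ndarray,
    y_cont: np.ndarray,
    gidx_c: np.ndarray,
    G: int,
    nodes: np.ndarray,
    weights: np.ndarray,
) -> float:
    p = Xd.shape[1]
    beta_d = params[:p]
    beta_c = params[p : 2 * p]
    a = np.exp(params[2 * p])
    b = params[2 * p + 1]
    sig = np.exp(params[2 * p + 2])
    xb_d = Xd @ beta_d
    r = y_cont - Xc @ beta_c
    n_det = np.bincount(gidx_c, minlength=G).astype(float)
    Sr = np.bincount(gidx_c, r, minlength=G)
    # Newton for the per-donor posterior mode of u
    u = np.zeros(G)
    for _ in range(50):
        eta = xb_d + a * u[gidx]
        mu = special.expit(eta)
        grad = (
            a * np.bincount(gidx, y_det - mu, minlength=G)
            + b * (Sr - b * u * n_det) / sig**2
            - u
        )
        hess = -(a**2) * np.bincount(gidx, mu * (1 - mu), minlength=G) - n_det * b**2 / sig**2 - 1.0
        step = grad / hess
        u = u - step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = xb_d + a * u[gidx]
    mu = special.expit(eta)
    curv = a**2 * np.bincount(gidx, mu * (1 - mu), minlength=G) + n_det * b**2 / sig**2 + 1.0
    tau = 1.0 / np.sqrt(curv)
    pts = u[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]
    logh = np.empty((G, nodes.size))
    const_c = -0.5 * np.log(2 * np.pi * sig**2)
    Sr2 = np.bincount(gidx_c, r**2, minlength=G)
    for k in range(nodes.size):
        eta_k = xb_d + a * pts[gidx, k]
        disc = np.bincount(gidx, _log_expit_terms(eta_k, y_det), minlength=G)
        bu = b * pts[:, k]
        cont = n_det * const_c - (Sr2 - 2 * bu * Sr + n_det * bu**2) / (2 * sig**2)
        logh[:, k] = disc + cont - 0.5 * pts[:, k] ** 2
    log_integrand = logh + nodes[None, :] ** 2 + np.log(weights)[None, :]
    mx = log_integrand.max(axis=1)
    log_int = mx + np.log(np.exp(log_integrand - mx[:, None]).sum(axis=1))
    log_int += 0.5 * np.log(2.0) + np.log(tau) - 0.5 * np.log(2.0 * np.pi)
    return float(log_int.sum())


def fit_joint_hurdle(
    X: np.ndarray,
    counts_log2: np.ndarray,
    detected: np.ndarray,
    groups: np.ndarray,
    n_nodes: int = 9,
) -> JointHurdleFit:
    """ML fit of the shared-random-intercept two-part hurdle."""
    X = np.asarray(X, dtype=float)
    detected = np.asarray(detected, dtype=float)
    _, gidx = np.unique(groups, return_inverse=True)
    G = int(gidx.max()) + 1
    det_mask = detected > 0
    Xc = X[det_mask]
    yc = np.asarray(counts_log2, dtype=float)[det_mask]
    gidx_c = gidx[det_mask]
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)

    # warm start from the separate-parts fits
    disc = fit_logistic_mixed(X, detected, groups, n_nodes=n_nodes)
    cont = fit_linear_mixed(Xc, yc, gidx_c)
    p = X.shape[1]
    p0 = np.concatenate(
        [
            disc.params,
            cont.params,
            [np.log(max(disc.sigma, 1e-3)), max(cont.tau, 1e-3), np.log(max(cont.sigma, 1e-3))],
        ]
    )

    def negll(q):
        return -_joint_loglik(q, X, detected, gidx, Xc, yc, gidx_c, G, nodes, weights)

    res = optimize.minimize(negll, p0, method="L-BFGS-B", options={"maxiter": 400})
    ok = bool(res.success) and np.isfinite(res.fun)
    q = res.x if ok else p0
    ll = _joint_loglik(q, X, detected, gidx, Xc, yc, gidx_c, G, nodes, weights)
    return JointHurdleFit(
        beta_discrete=q[:p],
        beta_continuous=q[p : 2 * p],
        loading_discrete=float(np.exp(q[2 * p])),
        loading_continuous=float(q[2 * p + 1]),
        sigma_resid=float(np.exp(q[2 * p + 2])),
        loglik=float(ll),
        converged=ok,
    )


@dataclass
class LogisticMixedFit:
    params: np.ndarray  # fixed-effect coefficients
    sigma: float  # random-intercept SD
    loglik: float
    converged: bool
    fallback: str | None = None  # "fixed" when the mixed fit failed


def fit_logistic_mixed(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    n_nodes: int = 9,
    ridge: float = 0.0,
) -> LogisticMixedFit:
    """ML fit of logit P(y=1) = X beta + u_group, u ~ N(0, sigma^2).

    ``ridge`` adds an L2 penalty on beta (excluding the first column if it is
    an intercept) used to stabilize separated fits; the returned loglik is
    the unpenalized likelihood at the penalized optimum.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    uniq, gidx = np.unique(groups, return_inverse=True)
    data = _GroupData(X, y, gidx)
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)

    def negll(p):
        val = -_marginal_loglik(p, data, nodes, weights)
        if ridge > 0:
            val += 0.5 * ridge * np.sum(p[:-1] ** 2)
        return val

    # warm start from a plain logistic fit
    try:
        from statsmodels.api import GLM, families

        glm = GLM(y, X, family=families.Binomial()).fit(maxiter=50)
        beta0 = np.asarray(glm.params)
        if not np.all(np.isfinite(beta0)) or np.abs(beta0).max() > 20:
            raise ValueError("separation")
    except Exception:
        beta0 = np.zeros(X.shape[1])
    p0 = np.concatenate([beta0, [np.log(0.3)]])
    res = optimize.minimize(negll, p0, method="L-BFGS-B", options={"maxiter": 300})
    ok = bool(res.success) and np.all(np.isfinite(res.x))
    if not ok and ridge == 0.0:
        return fit_logistic_mixed(X, y, groups, n_nodes=n_nodes, ridge=1e-3)
    ll = _marginal_loglik(res.x, data, nodes, weights)
    return LogisticMixedFit(
        params=res.x[:-1],
        sigma=float(np.exp(res.x[-1])),
        loglik=float(ll),
        converged=ok,
        fallback="ridge" if ridge > 0 else None,
    )
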