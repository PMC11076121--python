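"""Mixed-model numerics shared by the metrics and inference modules.

Gaussian linear mixed models with a single random intercept admit a
closed-form profile of the (RE)ML criterion over the variance ratio
``lambda = sigma2_group / sigma2_resid``: for fixed lambda the model reduces
to ordinary least squares on group-mean-shrunk data (the classical
random-effects transform), so fitting is a one-dimensional optimisation.
That makes each fit ~microseconds, which the node-permutation null (10^5-10^6
refits) requires.  Results are cross-checked against statsmodels MixedLM in
the test suite.

The Poisson mixed model (one random intercept) is fitted by maximum
likelihood with Gauss-Hermite quadrature over the random effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

_TWO_PI = 2.0 * np.pi


def _group_structure(groups: np.ndarray):
    """Return (codes, counts, sorted order) for a group label array."""
    codes, inverse = np.unique(groups, return_inverse=True)
    order = np.argsort(inverse, kind="stable")
    counts = np.bincount(inverse)
    return inverse, counts, order


def _shrink(M: np.ndarray, inv: np.ndarray, counts: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Subtract theta_g * group mean from every row of M (rows grouped by inv)."""
    sums = np.zeros((len(counts),) + M.shape[1:])
    np.add.at(sums, inv, M)
    means = sums / counts.reshape(-1, *([1] * (M.ndim - 1)))
    th = theta[inv] if M.ndim == 1 else theta[inv][:, None]
    return M - th * means[inv]


@dataclass
class LMMFit:
    """Random-intercept Gaussian LMM fit."""

    beta: np.ndarray
    se: np.ndarray
    sigma2_group: float
    sigma2_resid: float
    loglike: float
    reml: bool
    converged: bool = True

    @property
    def icc(self) -> float:
        tot = self.sigma2_group + self.sigma2_resid
        return float(self.sigma2_group / tot) if tot > 0 else 0.0


def _neg2_profiled(rho: float, y, X, inv, counts, reml: bool):
    """-2 log-likelihood profiled over beta and sigma2, at rho = lam/(1+lam)."""
    lam = rho / (1.0 - rho)
    theta = 1.0 - 1.0 / np.sqrt(1.0 + counts * lam)
    yt = _shrink(y, inv, counts, theta)
    Xt = _shrink(X, inv, counts, theta)
    G = Xt.T @ Xt
    xy = Xt.T @ yt
    beta = np.linalg.solve(G, xy)
    Q = float(yt @ yt - xy @ beta)
    n, p = X.shape
    logdet_w = float(np.sum(np.log1p(counts * lam)))
    if reml:
        dof = n - p
        sign, logdet_g = np.linalg.slogdet(G)
        crit = dof * (np.log(_TWO_PI) + 1.0 + np.log(max(Q, 1e-300) / dof)) + logdet_w + logdet_g
    else:
        dof = n
        crit = n * (np.log(_TWO_PI) + 1.0 + np.log(max(Q, 1e-300) / n)) + logdet_w
    return crit, beta, Q, G


def ri_lmm_fit(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    reml: bool = True,
) -> LMMFit:
    """Fit ``y = X beta + b_group + e`` with one random intercept.

    Parameters
    ----------
    y, X
        Response vector (n,) and design matrix (n, p) including a constant
        column if an intercept is wanted.
    groups
        Group label per row (any hashable dtype).
    reml
        Restricted maximum likelihood (default) or plain ML.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    inv, counts, _ = _group_structure(np.asarray(groups))

    def crit(rho):
        return _neg2_profiled(rho, y, X, inv, counts, reml)[0]

    res = optimize.minimize_scalar(crit, bounds=(0.0, 1.0 - 1e-9), method="bounded",
                                   options={"xatol": 1e-10})
    rho = float(res.x)
    if crit(0.0) <= res.fun:  # boundary solution: no among-group variance
        rho = 0.0
    c, beta, Q, G = _neg2_profiled(rho, y, X, inv, counts, reml)
    n, p = X.shape
    dof = n - p if reml else n
    sigma2_e = Q / dof
    lam = rho / (1.0 - rho)
    se = np.sqrt(np.diag(np.linalg.inv(G)) * sigma2_e)
    return LMMFit(
        beta=beta,
        se=se,
        sigma2_group=lam * sigma2_e,
        sigma2_resid=sigma2_e,
        loglike=-0.5 * c,
        reml=reml,
    )


def ri_lmm_lrt(y: np.ndarray, X: np.ndarray, groups: np.ndarray, term: int):
    """1-d.f. likelihood-ratio chi-square for dropping column *term* (ML fits)."""
    full = ri_lmm_fit(y, X, groups, reml=False)
    reduced = ri_lmm_fit(y, np.delete(X, term, axis=1), groups, reml=False)
    chi2 = max(0.0, 2.0 * (full.loglike - reduced.loglike))
    return chi2, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Batched grid fits (permutation engine)
# ---------------------------------------------------------------------------

def ri_lmm_grid_fit(
    Y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    reml: bool = True,
    rho_grid: np.ndarray | None = None,
) -> np.ndarray:
    """Fit the random-intercept LMM to every column of ``Y`` at once.

    The variance ratio is profiled on a fixed grid of ``rho = lam/(1+lam)``
    values (fine enough that coefficient error is negligible next to
    permutation spread); each column gets its own grid-argmin.  Returns the
    (p, B) matrix of fixed-effect estimates.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    X = np.asarray(X, dtype=float)
    inv, counts, _ = _group_structure(np.asarray(groups))
    n, p = X.shape
    nb = Y.shape[1]
    if rho_grid is None:
        rho_grid = np.concatenate([[0.0], np.linspace(0.005, 0.995, 199)])
    best_crit = np.full(nb, np.inf)
    best_beta = np.zeros((p, nb))
    dof = n - p if reml else n
    for rho in rho_grid:
        lam = rho / (1.0 - rho)
        theta = 1.0 - 1.0 / np.sqrt(1.0 + counts * lam)
        Xt = _shrink(X, inv, counts, theta)
        Yt = _shrink(Y, inv, counts, theta)
        G = Xt.T @ Xt
        XtY = Xt.T @ Yt
        B = np.linalg.solve(G, XtY)
        Q = np.maximum(np.einsum("ij,ij->j", Yt, Yt) - np.einsum("ij,ij->j", XtY, B), 1e-300)
        logdet_w = float(np.sum(np.log1p(counts * lam)))
        if reml:
            _, logdet_g = np.linalg.slogdet(G)
            crit = dof * np.log(Q / dof) + logdet_w + logdet_g
        else:
            crit = n * np.log(Q / n) + logdet_w
        better = crit < best_crit
        if better.any():
            best_crit[better] = crit[better]
            best_beta[:, better] = B[:, better]
    return best_beta


# ---------------------------------------------------------------------------
# Poisson GLMM (one random intercept) by Gauss-Hermite ML
# ---------------------------------------------------------------------------

@dataclass
class PoissonGLMMFit:
    beta: np.ndarray
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    tau: float  # random-intercept SD
    loglike: float
    converged: bool


def _poisson_glmm_nll(params, y, X, inv, n_groups, nodes, weights):
    """Negative marginal log-likelihood via adaptive Gauss-Hermite quadrature.

    The quadrature is recentred and rescaled at each group's posterior mode
    (found by a few Newton steps on the concave log-integrand), matching the
    accuracy of adaptive-GQ fitters at modest node counts.
    """
    beta = params[:-1]
    tau = np.exp(params[-1])
    eta = X @ beta
    sum_y_eta = np.zeros(n_groups)
    np.add.at(sum_y_eta, inv, y * eta)
    sum_y = np.zeros(n_groups)
    np.add.at(sum_y, inv, y)
    sum_mu = np.zeros(n_groups)
    np.add.at(sum_mu, inv, np.exp(eta))
    # mode of g(b) = sum_y b - sum_mu e^b - b^2 / (2 tau^2), per group
    m = np.zeros(n_groups)
    for _ in range(25):
        e = sum_mu * np.exp(m)
        grad = sum_y - e - m / tau**2
        hess = -e - 1.0 / tau**2
        step = np.clip(grad / hess, -2.0, 2.0)
        m = m - step
        if np.max(np.abs(step)) < 1e-10:
            break
    sd = 1.0 / np.sqrt(sum_mu * np.exp(m) + 1.0 / tau**2)
    # adaptive GH: int e^{g} db ~ sqrt(2) sd sum_q w_q e^{z_q^2} e^{g(m + sqrt2 sd z_q)}
    b = m[:, None] + np.sqrt(2.0) * sd[:, None] * nodes[None, :]
    g = (
        sum_y[:, None] * b
        - sum_mu[:, None] * np.exp(b)
        - b**2 / (2.0 * tau**2)
    )
    lw = np.log(weights)[None, :] + nodes[None, :] ** 2 + g
    peak = lw.max(axis=1, keepdims=True)
    log_int = np.log(np.sum(np.exp(lw - peak), axis=1)) + peak[:, 0]
    ll = np.sum(
        sum_y_eta + log_int + 0.5 * np.log(2.0) + np.log(sd)
        - np.log(tau) - 0.5 * np.log(2.0 * np.pi)
    )
    ll -= np.sum(special.gammaln(y + 1.0))
    return -ll


def poisson_glmm_fit(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    n_quad: int = 30,
) -> PoissonGLMMFit:
    """ML fit of a Poisson GLMM with one random intercept.

    The random-effect integral is evaluated by Gauss-Hermite quadrature
    (*n_quad* nodes); Wald z statistics come from the numerical Hessian at
    the optimum.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    inv, counts, _ = _group_structure(np.asarray(groups))
    n_groups = len(counts)
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)

    # start from a plain Poisson GLM
    import statsmodels.api as sm

    glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    x0 = np.concatenate([glm.params, [np.log(0.3)]])
    res = optimize.minimize(
        _poisson_glmm_nll, x0, args=(y, X, inv, n_groups, nodes, weights),
        method="BFGS", options={"gtol": 1e-7, "maxiter": 500},
    )
    p = X.shape[1]
    from statsmodels.tools.numdiff import approx_hess

    H = approx_hess(res.x, _poisson_glmm_nll, args=(y, X, inv, n_groups, nodes, weights))
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se_all = np.full(p + 1, np.nan)
    beta = res.x[:p]
    se = se_all[:p]
    z = beta / se
    return PoissonGLMMFit(
        beta=beta,
        se=se,
        zvalues=z,
        pvalues=2.0 * stats.norm.sf(np.abs(z)),
        tau=float(np.exp(res.x[-1])),
        loglike=float(-res.fun),
        converged=bool(res.success),
    )
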