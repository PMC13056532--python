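"""Two-level random-intercept linear model with profiled REML/ML estimation.

Model: y_ij = x_ij' beta + u_j + e_ij with u_j ~ N(0, sigma2_u) for stratum j
and e_ij ~ N(0, sigma2_e).  With a single grouping factor the covariance is
V = sigma2_e * (I + psi * Z Z'), psi = sigma2_u / sigma2_e, and both the GLS
solve and the determinants reduce to per-group sufficient statistics:

    (I + psi * J_nj)^-1 = I - psi/(1 + psi*nj) * J_nj
    log|I + psi ZZ'|    = sum_j log(1 + psi*nj)

so one evaluation of the profiled criterion costs O(q p^2) after a single
O(n p) pass.  The criterion is minimised over log(psi) by bounded scalar
search (tolerance 1e-8 on the relative criterion), with the boundary
sigma2_u = 0 checked explicitly and flagged.  If the between-group mean
square falls below the within mean square the estimate truncates at the
boundary rather than going negative.

Standard errors of the variance components come from the numerically
differentiated observed information of the (restricted) log-likelihood in
(sigma2_u, sigma2_e); they are NaN at the boundary where the Wald
approximation does not apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

_LOG_PSI_LO, _LOG_PSI_HI = -30.0, 15.0


class SingularDesignError(ValueError):
    """Design matrix is rank deficient."""


class DegenerateDataError(ValueError):
    """Residual variance is (numerically) zero."""


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge; carries the optimizer trace."""


@dataclass
class LinearFit:
    beta: pd.Series
    cov_beta: pd.DataFrame
    sigma2_u: float
    sigma2_e: float
    se_sigma2_u: float
    se_sigma2_e: float
    loglik: float
    method: str
    converged: bool
    n_iter: int
    boundary: bool
    group_levels: np.ndarray = field(repr=False)
    n_j: np.ndarray = field(repr=False)
    n: int = 0
    p: int = 0

    def to_dict(self) -> dict:
        return {
            "beta": {k: float(v) for k, v in self.beta.items()},
            "cov_beta": self.cov_beta.to_numpy().tolist(),
            "sigma2_u": self.sigma2_u,
            "sigma2_e": self.sigma2_e,
            "se_sigma2_u": self.se_sigma2_u,
            "se_sigma2_e": self.se_sigma2_e,
            "loglik": self.loglik,
            "method": self.method,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "boundary": self.boundary,
            "n": self.n,
            "n_groups": int(len(self.group_levels)),
        }


def _prepare(y, X, groups):
    y = np.asarray(y, dtype=float).ravel()
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        names = [f"x{i}" for i in range(Xv.shape[1])]
    n, p = Xv.shape
    if len(y) != n:
        raise ValueError("y and X have different lengths")
    if n <= p:
        raise ValueError("need more observations than design columns")
    codes, levels = pd.factorize(np.asarray(groups), sort=True)
    if (codes < 0).any():
        raise ValueError("missing stratum identifiers")
    if len(levels) < 2:
        raise ValueError("need at least 2 non-empty strata")
    rank = np.linalg.matrix_rank(Xv)
    if rank < p:
        # identify the pivoted-out columns via rank-revealing QR
        _, R, piv = linalg.qr(Xv, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        bad = [names[j] for j in piv[rank:]] if diag.size else names
        raise SingularDesignError(f"singular design matrix; collinear columns: {sorted(bad)}")
    return y, Xv, names, codes, np.asarray(levels), n, p


def _suffstats(y, Xv, codes, q):
    XtX = Xv.T @ Xv
    Xty = Xv.T @ y
    yty = float(y @ y)
    p = Xv.shape[1]
    S = np.zeros((q, p))
    np.add.at(S, codes, Xv)
    T = np.bincount(codes, weights=y, minlength=q)
    n_j = np.bincount(codes, minlength=q).astype(float)
    return XtX, Xty, yty, S, T, n_j


def _gls(psi, XtX, Xty, yty, S, T, n_j):
    """GLS pieces at variance ratio psi: beta-hat, RSS under H^-1, log|H|, log|X'H^-1X|."""
    c = psi / (1.0 + psi * n_j)
    A = XtX - (S.T * c) @ S
    b = Xty - S.T @ (c * T)
    cf = linalg.cho_factor(A)
    beta = linalg.cho_solve(cf, b)
    yHy = yty - float(c @ (T * T))
    rss = yHy - float(beta @ b)
    logdetH = float(np.sum(np.log1p(psi * n_j)))
    logdetA = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return beta, A, rss, logdetH, logdetA


def _profiled_criterion(psi, stats, n, p, reml):
    _, _, rss, logdetH, logdetA = _gls(psi, *stats)
    if rss <= 0:
        raise DegenerateDataError("zero within-stratum residual variance; model is degenerate")
    if reml:
        return (n - p) * np.log(rss) + logdetH + logdetA
    return n * np.log(rss) + logdetH


def _minus2_loglik(sigma2_u, sigma2_e, stats, n, p, reml):
    """Full -2 log(restricted) likelihood at given variance components."""
    psi = sigma2_u / sigma2_e
    _, _, rss, logdetH, logdetA = _gls(psi, *stats)
    if reml:
        return ((n - p) * (np.log(2 * np.pi) + np.log(sigma2_e)) + logdetH + logdetA
                + rss / sigma2_e)
    return n * (np.log(2 * np.pi) + np.log(sigma2_e)) + logdetH + rss / sigma2_e


def fit_linear(y, X, groups, method: str = "reml", tol: float = 1e-8) -> LinearFit:
    """Fit the random-intercept linear model by profiled REML (default) or ML.

    ``groups`` are stratum identifiers (any hashable labels); estimates are
    invariant to record order and to relabeling.  The boundary estimate
    sigma2_u = 0 is allowed and flagged.
    """
    method = method.lower()
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    reml = method == "reml"
    y, Xv, names, codes, levels, n, p = _prepare(y, X, groups)
    if np.ptp(y) == 0.0:
        raise DegenerateDataError("outcome is constant; residual variance would be zero")
    q = len(levels)
    stats = _suffstats(y, Xv, codes, q)

    def crit(log_psi):
        return _profiled_criterion(np.exp(log_psi), stats, n, p, reml)

    res = optimize.minimize_scalar(
        crit, bounds=(_LOG_PSI_LO, _LOG_PSI_HI), method="bounded",
        options={"xatol": min(tol, 1e-10), "maxiter": 500},
    )
    if not res.success:
        raise ConvergenceError(f"profiled-likelihood search failed: {res.message}")
    psi_hat = float(np.exp(res.x))
    # explicit boundary comparison at psi = 0 (OLS)
    crit_zero = _profiled_criterion(0.0, stats, n, p, reml)
    boundary = crit_zero <= res.fun + 1e-10 or res.x <= _LOG_PSI_LO + 1e-6
    if boundary:
        psi_hat = 0.0

    beta, A, rss, logdetH, logdetA = _gls(psi_hat, *stats)
    dof = n - p if reml else n
    sigma2_e = rss / dof
    if sigma2_e <= 0 or not np.isfinite(sigma2_e):
        raise DegenerateDataError("estimated residual variance is not positive")
    sigma2_u = psi_hat * sigma2_e
    cov_beta = sigma2_e * linalg.inv(A)
    loglik = -0.5 * _minus2_loglik(sigma2_u, sigma2_e, stats, n, p, reml)

    se_u, se_e = _variance_ses(sigma2_u, sigma2_e, stats, n, p, reml, boundary)

    return LinearFit(
        beta=pd.Series(beta, index=names),
        cov_beta=pd.DataFrame(cov_beta, index=names, columns=names),
        sigma2_u=float(sigma2_u),
        sigma2_e=float(sigma2_e),
        se_sigma2_u=se_u,
        se_sigma2_e=se_e,
        loglik=float(loglik),
        method=method,
        converged=True,
        n_iter=int(res.nit),
        boundary=bool(boundary),
        group_levels=levels,
        n_j=stats[5].astype(int),
        n=n,
        p=p,
    )


def _variance_ses(sigma2_u, sigma2_e, stats, n, p, reml, boundary):
    """Wald SEs from the numerically differentiated observed information."""
    if boundary:
        # one-sided problem at sigma2_u = 0: only the residual variance has a
        # meaningful Wald SE (asymptotic 2*sigma2_e^2/(n-p))
        dof = n - p if reml else n
        return float("nan"), float(np.sqrt(2.0 * sigma2_e**2 / dof))
    theta = np.array([sigma2_u, sigma2_e])
    h = np.maximum(1e-7, 1e-5 * theta)

    def f(t):
        return _minus2_loglik(t[0], t[1], stats, n, p, reml)

    H = np.empty((2, 2))
    for i in range(2):
        for j in range(i, 2):
            ti = np.zeros(2); ti[i] = h[i]
            tj = np.zeros(2); tj[j] = h[j]
            H[i, j] = H[j, i] = (
                f(theta + ti + tj) - f(theta + ti - tj) - f(theta - ti + tj) + f(theta - ti - tj)
            ) / (4 * h[i] * h[j])
    try:
        cov = 2.0 * linalg.inv(H)
        var = np.diag(cov)
        if (var <= 0).any():
            return float("nan"), float("nan")
        return float(np.sqrt(var[0])), float(np.sqrt(var[1]))
    except linalg.LinAlgError:
        return float("nan"), float("nan")


def shrinkage_factor(sigma2_u: float, sigma2_e: float, n_j) -> np.ndarray:
    """lambda_j = sigma2_u / (sigma2_u + sigma2_e / n_j); 0 when sigma2_u = 0."""
    n_j = np.asarray(n_j, dtype=float)
    if sigma2_u == 0.0:
        return np.zeros_like(n_j)
    return sigma2_u / (sigma2_u + sigma2_e / np.maximum(n_j, 1e-300))


def linear_blups(fit: LinearFit, y, X, groups) -> pd.DataFrame:
    """Empirical-Bayes (BLUP) stratum intercepts for a fitted model.

    u_hat_j = lambda_j * (mean raw residual of stratum j); the posterior
    (conditional) SD is sqrt(sigma2_u * (1 - lambda_j)) and the 95% interval
    is u_hat +/- 1.96 * SD.  With sigma2_u = 0 every u_hat is exactly 0 with a
    degenerate interval.  Returns a frame indexed like ``fit.group_levels``
    with columns ``u_hat``, ``post_sd``, ``ci_lo``, ``ci_hi``, ``n``.
    """
    y = np.asarray(y, dtype=float).ravel()
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    codes = pd.Categorical(np.asarray(groups), categories=list(fit.group_levels)).codes
    if (codes < 0).any():
        raise ValueError("groups contain levels unseen by the fit")
    resid = y - Xv @ fit.beta.to_numpy()
    q = len(fit.group_levels)
    n_j = np.bincount(codes, minlength=q).astype(float)
    mean_resid = np.zeros(q)
    nonzero = n_j > 0
    mean_resid[nonzero] = np.bincount(codes, weights=resid, minlength=q)[nonzero] / n_j[nonzero]
    lam = shrinkage_factor(fit.sigma2_u, fit.sigma2_e, n_j)
    u_hat = lam * mean_resid
    post_sd = np.sqrt(np.maximum(fit.sigma2_u * (1.0 - lam), 0.0))
    # empty strata carry the prior: u_hat = 0 with SD sqrt(sigma2_u)
    u_hat[~nonzero] = 0.0
    post_sd[~nonzero] = np.sqrt(fit.sigma2_u)
    z = 1.959963984540054
    return pd.DataFrame(
        {
            "u_hat": u_hat,
            "post_sd": post_sd,
            "ci_lo": u_hat - z * post_sd,
            "ci_hi": u_hat + z * post_sd,
            "n": n_j.astype(int),
        },
        index=pd.Index(fit.group_levels, name="stratum"),
    )
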