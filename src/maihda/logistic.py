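"""Two-level random-intercept logistic model via adaptive Gauss-Hermite quadrature.

Model: logit P(y_ij = 1 | u_j) = x_ij' beta + u_j, u_j ~ N(0, sigma2_u).
The marginal likelihood integrates the random intercept out per stratum:

    L_j = int prod_i p_ij(u)^y (1-p_ij(u))^(1-y) phi(u; 0, sigma2_u) du

approximated by Gauss-Hermite quadrature adapted per stratum: nodes are
centred at the posterior mode of u_j (found by a vectorised Newton iteration
across strata) and scaled by the Laplace curvature there, which keeps a
modest order (default 15) accurate even for large strata.  Maximisation is
L-BFGS-B over (beta, sigma_u >= 0) with analytic gradients computed as
posterior expectations of the complete-data score under the same quadrature
rule.  Identical covariate rows within a stratum are aggregated with weights
first, which collapses models whose predictors are all categorical to at
most a few rows per stratum.

Wald covariance comes from the numerically differentiated observed
information at the optimum; odds-ratio CIs are exp(beta +/- 1.96 SE).  The
boundary sigma_u ~ 0 is allowed: the fit then reduces to (and is refitted
as) a plain logistic regression, flagged as a boundary estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.special import expit, logsumexp

_Z95 = 1.959963984540054
_SIGMA_FLOOR = 1e-6
_SIGMA_BOUNDARY = 1e-3


class SeparationError(ValueError):
    """Complete or quasi-complete separation detected (divergent coefficients)."""


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge; carries the optimizer trace."""


@dataclass
class LogisticFit:
    beta: pd.Series
    cov_beta: pd.DataFrame
    or_table: pd.DataFrame
    sigma2_u: float
    se_sigma2_u: float
    quadrature_order: int
    loglik: float
    converged: bool
    n_iter: int
    boundary: bool
    group_levels: np.ndarray = field(repr=False)
    n_j: np.ndarray = field(repr=False)
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "beta": {k: float(v) for k, v in self.beta.items()},
            "cov_beta": self.cov_beta.to_numpy().tolist(),
            "odds_ratios": {
                k: {"or": float(r["OR"]), "ci_lo": float(r["ci_lo"]), "ci_hi": float(r["ci_hi"])}
                for k, r in self.or_table.iterrows()
            },
            "sigma2_u": self.sigma2_u,
            "se_sigma2_u": self.se_sigma2_u,
            "quadrature_order": self.quadrature_order,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "boundary": self.boundary,
            "n": self.n,
            "n_groups": int(len(self.group_levels)),
        }


def _log1pexp(x):
    return np.logaddexp(0.0, x)


def _check_separation(beta, col_sd):
    scaled = np.abs(beta) * col_sd
    if np.max(scaled) > 50.0:
        raise SeparationError(
            "coefficients diverged (|beta| > 50 on standardized predictors); "
            "data are likely separated"
        )


def fit_plain_logistic(y, X, weights=None, max_iter=100, tol=1e-10):
    """Weighted logistic regression by Newton-Raphson; returns (beta, cov)."""
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    n, p = Xv.shape
    col_sd = Xv.std(axis=0)
    col_sd[col_sd == 0] = 1.0
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = Xv @ beta
        mu = expit(eta)
        grad = Xv.T @ (w * (y - mu))
        W = w * mu * (1.0 - mu)
        H = (Xv * W[:, None]).T @ Xv
        try:
            step = linalg.solve(H, grad, assume_a="pos")
        except linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix in logistic fit: {exc}") from exc
        beta = beta + step
        _check_separation(beta, col_sd)
        if np.max(np.abs(step)) < tol:
            break
    else:
        raise ConvergenceError("plain logistic regression did not converge")
    eta = Xv @ beta
    W = w * expit(eta) * (1.0 - expit(eta))
    cov = linalg.inv((Xv * W[:, None]).T @ Xv)
    return beta, cov


def _aggregate(y, Xv, codes):
    """Collapse identical (stratum, covariate-row, y) rows into weighted rows."""
    arr = np.column_stack([codes.astype(float), y, Xv])
    uniq, counts = np.unique(arr, axis=0, return_counts=True)
    ga = uniq[:, 0].astype(int)
    ya = uniq[:, 1]
    Xa = uniq[:, 2:]
    return ya, Xa, ga, counts.astype(float)


class _AGHQ:
    """Adaptive Gauss-Hermite machinery over one random intercept per stratum."""

    def __init__(self, ya, Xa, ga, w, q, order):
        self.ya, self.Xa, self.ga, self.w = ya, Xa, ga, w
        self.q = q
        self.order = order
        t, omega = np.polynomial.hermite.hermgauss(order)
        self.t = t
        self.log_omega = np.log(omega)
        self.modes = np.zeros(q)
        self.n_j = np.bincount(ga, weights=w, minlength=q)

    def _find_modes(self, eta0, sigma):
        m = self.modes.copy()
        inv_s2 = 1.0 / (sigma * sigma)
        for _ in range(100):
            p = expit(eta0 + m[self.ga])
            score = np.bincount(self.ga, weights=self.w * (self.ya - p), minlength=self.q) - m * inv_s2
            info = np.bincount(self.ga, weights=self.w * p * (1.0 - p), minlength=self.q) + inv_s2
            step = score / info
            np.clip(step, -5.0, 5.0, out=step)
            m += step
            if np.max(np.abs(step)) < 1e-11:
                break
        self.modes = m
        s = 1.0 / np.sqrt(info)
        return m, s

    def loglik_grad(self, beta, sigma):
        """(sum_j log L_j, gradient wrt (beta, sigma)) at the current parameters."""
        eta0 = self.Xa @ beta
        m, s = self._find_modes(eta0, sigma)
        sqrt2 = np.sqrt(2.0)
        u = m[:, None] + sqrt2 * s[:, None] * self.t[None, :]          # (q, K)
        eta = eta0[:, None] + u[self.ga, :]                            # (R, K)
        contrib = self.w[:, None] * (self.ya[:, None] * eta - _log1pexp(eta))
        ll_data = np.zeros((self.q, self.order))
        np.add.at(ll_data, self.ga, contrib)
        log_phi = -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * (u / sigma) ** 2
        h = ll_data + log_phi + self.log_omega[None, :] + self.t[None, :] ** 2
        log_Lj = np.log(sqrt2 * s) + logsumexp(h, axis=1)
        loglik = float(np.sum(log_Lj))
        # posterior node weights
        W = np.exp(h - log_Lj[:, None] + np.log(sqrt2 * s)[:, None])   # rows sum to 1
        p = expit(eta)                                                 # (R, K)
        resid = self.w[:, None] * (self.ya[:, None] - p) * W[self.ga, :]
        grad_beta = self.Xa.T @ resid.sum(axis=1)
        grad_sigma = float(np.sum(W * (u * u / sigma**3 - 1.0 / sigma)))
        return loglik, np.append(grad_beta, grad_sigma)

    def posterior_modes(self, beta, sigma):
        eta0 = self.Xa @ beta
        return self._find_modes(eta0, sigma)


def fit_logistic(y, X, groups, quadrature_order: int = 15, fix_sigma_u: float | None = None,
                 max_iter: int = 300) -> LogisticFit:
    """Fit the random-intercept logistic model by adaptive-GHQ maximum likelihood.

    ``fix_sigma_u`` pins the random-intercept SD instead of estimating it;
    ``fix_sigma_u=0`` reduces the model to plain logistic regression (used by
    oracle checks).  Raises :class:`SeparationError` on divergent
    coefficients and :class:`ConvergenceError` on optimizer failure.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        names = [f"x{i}" for i in range(Xv.shape[1])]
    codes, levels = pd.factorize(np.asarray(groups), sort=True)
    if (codes < 0).any():
        raise ValueError("missing stratum identifiers")
    if len(levels) < 2:
        raise ValueError("need at least 2 non-empty strata")
    if quadrature_order < 2:
        raise ValueError("quadrature_order must be >= 2")
    n = len(y)
    p = Xv.shape[1]
    col_sd = Xv.std(axis=0)
    col_sd[col_sd == 0] = 1.0

    ya, Xa, ga, w = _aggregate(y, Xv, codes)
    q = len(levels)
    n_j = np.bincount(codes, minlength=q)

    beta0, cov0 = fit_plain_logistic(ya, Xa, weights=w)

    if fix_sigma_u is not None and fix_sigma_u == 0.0:
        or_table = _or_table(beta0, np.sqrt(np.diag(cov0)), names)
        eta = Xa @ beta0
        ll = float(np.sum(w * (ya * eta - _log1pexp(eta))))
        return LogisticFit(
            beta=pd.Series(beta0, index=names),
            cov_beta=pd.DataFrame(cov0, index=names, columns=names),
            or_table=or_table, sigma2_u=0.0, se_sigma2_u=float("nan"),
            quadrature_order=quadrature_order, loglik=ll, converged=True,
            n_iter=0, boundary=True, group_levels=np.asarray(levels),
            n_j=n_j, n=n,
        )

    aghq = _AGHQ(ya, Xa, ga, w, q, quadrature_order)

    if fix_sigma_u is not None:
        sigma_fixed = float(fix_sigma_u)

        def fun(theta):
            ll, g = aghq.loglik_grad(theta, sigma_fixed)
            return -ll, -g[:-1]

        res = optimize.minimize(fun, beta0, jac=True, method="L-BFGS-B",
                                options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-7})
        if not res.success:
            raise ConvergenceError(f"logistic AGHQ fit failed: {res.message}")
        beta_hat, sigma_hat = res.x, sigma_fixed
        theta_hat = np.append(beta_hat, sigma_hat)
        free = slice(0, p)
    else:
        theta0 = np.append(beta0, 0.3)
        bounds = [(None, None)] * p + [(_SIGMA_FLOOR, 25.0)]

        def fun(theta):
            ll, g = aghq.loglik_grad(theta[:-1], theta[-1])
            return -ll, -g

        res = optimize.minimize(fun, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-7})
        if not res.success:
            raise ConvergenceError(f"logistic AGHQ fit failed: {res.message}")
        theta_hat = res.x
        beta_hat, sigma_hat = theta_hat[:-1], float(theta_hat[-1])
        free = slice(0, p + 1)

    _check_separation(beta_hat, col_sd)
    boundary = sigma_hat <= _SIGMA_BOUNDARY

    if boundary and fix_sigma_u is None:
        # at the boundary the Laplace/GHQ fit degenerates to plain logistic
        beta_hat, cov = fit_plain_logistic(ya, Xa, weights=w)
        eta = Xa @ beta_hat
        ll = float(np.sum(w * (ya * eta - _log1pexp(eta))))
        se_beta = np.sqrt(np.diag(cov))
        return LogisticFit(
            beta=pd.Series(beta_hat, index=names),
            cov_beta=pd.DataFrame(cov, index=names, columns=names),
            or_table=_or_table(beta_hat, se_beta, names),
            sigma2_u=0.0, se_sigma2_u=float("nan"),
            quadrature_order=quadrature_order, loglik=ll, converged=True,
            n_iter=int(res.nit), boundary=True, group_levels=np.asarray(levels),
            n_j=n_j, n=n,
        )

    loglik, _ = aghq.loglik_grad(beta_hat, sigma_hat)
    H = _numerical_hessian(aghq, theta_hat, free)
    try:
        cov_all = linalg.inv(H)
    except linalg.LinAlgError:
        cov_all = np.full_like(H, np.nan)
    cov_beta = cov_all[:p, :p]
    se_beta = np.sqrt(np.abs(np.diag(cov_beta)))
    if fix_sigma_u is None:
        se_sigma = float(np.sqrt(abs(cov_all[p, p])))
        se_sigma2 = 2.0 * sigma_hat * se_sigma          # delta method to the variance scale
    else:
        se_sigma2 = float("nan")

    return LogisticFit(
        beta=pd.Series(beta_hat, index=names),
        cov_beta=pd.DataFrame(cov_beta, index=names, columns=names),
        or_table=_or_table(beta_hat, se_beta, names),
        sigma2_u=float(sigma_hat**2),
        se_sigma2_u=se_sigma2,
        quadrature_order=quadrature_order,
        loglik=float(loglik),
        converged=True,
        n_iter=int(res.nit),
        boundary=bool(boundary),
        group_levels=np.asarray(levels),
        n_j=n_j,
        n=n,
    )


def _or_table(beta, se, names):
    beta = np.asarray(beta)
    se = np.asarray(se)
    return pd.DataFrame(
        {
            "OR": np.exp(beta),
            "ci_lo": np.exp(beta - _Z95 * se),
            "ci_hi": np.exp(beta + _Z95 * se),
        },
        index=pd.Index(names, name="term"),
    )


def _numerical_hessian(aghq, theta_hat, free):
    """Observed information of -loglik by central differences of the analytic gradient."""
    idx = np.arange(len(theta_hat))[free]
    k = len(idx)
    H = np.zeros((k, k))
    for col, i in enumerate(idx):
        h = max(1e-6, 1e-6 * abs(theta_hat[i]))
        tp = theta_hat.copy(); tp[i] += h
        tm = theta_hat.copy(); tm[i] = max(tm[i] - h, _SIGMA_FLOOR) if i == len(theta_hat) - 1 else tm[i] - h
        _, gp = aghq.loglik_grad(tp[:-1], tp[-1])
        _, gm = aghq.loglik_grad(tm[:-1], tm[-1])
        H[:, col] = -(gp[free] - gm[free]) / (tp[i] - tm[i])
    return 0.5 * (H + H.T)


def logistic_eb_intercepts(fit: LogisticFit, y, X, groups) -> pd.DataFrame:
    """Empirical-Bayes stratum intercepts: posterior mode of u_j with Laplace SD.

    The 95% interval is mode +/- 1.96*SD.  With sigma2_u = 0 every u_hat is 0
    with a degenerate interval.  Strata with no records carry the prior mode 0
    with SD sigma_u.
    """
    y = np.asarray(y, dtype=float).ravel()
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    codes = pd.Categorical(np.asarray(groups), categories=list(fit.group_levels)).codes
    if (codes < 0).any():
        raise ValueError("groups contain levels unseen by the fit")
    q = len(fit.group_levels)
    n_j = np.bincount(codes, minlength=q)
    index = pd.Index(fit.group_levels, name="stratum")
    if fit.sigma2_u == 0.0:
        zeros = np.zeros(q)
        return pd.DataFrame({"u_hat": zeros, "post_sd": zeros, "ci_lo": zeros,
                             "ci_hi": zeros, "n": n_j}, index=index)
    sigma = np.sqrt(fit.sigma2_u)
    ya, Xa, ga, w = _aggregate(y, Xv, codes)
    aghq = _AGHQ(ya, Xa, ga, w, q, fit.quadrature_order)
    m, s = aghq.posterior_modes(fit.beta.to_numpy(), sigma)
    empty = n_j == 0
    m[empty] = 0.0
    s[empty] = sigma
    return pd.DataFrame(
        {"u_hat": m, "post_sd": s, "ci_lo": m - _Z95 * s, "ci_hi": m + _Z95 * s, "n": n_j},
        index=index,
    )
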