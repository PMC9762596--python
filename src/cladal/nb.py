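"""Negative-binomial regression: GLM and random-intercept GLMM.

Both models use the NB2 parameterisation with a log link:

    y ~ NB(mu, theta),  Var(y) = mu + mu^2 / theta,  log mu = X beta [+ b]

The GLM maximises the likelihood by alternating Fisher-scoring IRLS
updates of beta with Newton updates of the dispersion theta (the
classic glm.nb alternation).  The GLMM adds a normal random intercept
b ~ N(0, sigma_b^2) per group (host) and maximises the marginal
likelihood, integrating b out by adaptive Gauss-Hermite quadrature
(7 points by default; 1 point is the Laplace approximation).

Standard errors come from the observed information at the optimum;
Wald p-values use the normal reference for z = coef / se.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats

THETA_MIN = 1e-3
THETA_MAX = 1e6
LOG_SIGMA_MIN = -6.0  # sigma ~ 0.0025: effectively no host heterogeneity
LOG_SIGMA_MAX = 3.0
_ETA_CLIP = 30.0


class DegenerateDataError(ValueError):
    """Response carries no information (e.g. all zeros)."""


def nb_loglike(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """NB2 log-likelihood, summed over observations."""
    return float(np.sum(_nb_ll_terms(y, mu, theta)))


def _nb_ll_terms(y, mu, theta):
    return (special.gammaln(y + theta) - special.gammaln(theta)
            - special.gammaln(y + 1.0)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu)))


def wald_p(coef: float, se: float) -> float:
    """Two-sided normal-reference p-value for z = coef / se."""
    if not se > 0:
        raise ValueError(f"standard error must be positive, got {se}")
    return float(2.0 * stats.norm.sf(abs(coef) / se))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Monotone, capped at 1, order-preserving; invariant to input
    permutation up to reordering.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _validate_design(y, X):
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("y must be 1-d with one row of X per observation")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must contain non-negative integer counts")
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if np.all(y == 0):
        raise DegenerateDataError("response is identically zero")
    return y, X


class NBResultsBase:
    """Shared results surface: estimates, SEs, Wald inference, summary."""

    def __init__(self, model, params, bse, theta, llf, converged, n_iter,
                 theta_boundary=False):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.bse = np.asarray(bse, dtype=float)
        self.theta = float(theta)
        self.llf = float(llf)
        self.converged = bool(converged)
        self.n_iter = int(n_iter)
        self.theta_boundary = bool(theta_boundary)

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return np.array([wald_p(c, s) if s > 0 else np.nan
                         for c, s in zip(self.params, self.bse)])

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "coef": self.params,
            "std err": self.bse,
            "z": self.tvalues,
            "P>|z|": self.pvalues,
        }, index=self.model.exog_names)
        df.attrs["theta"] = self.theta
        df.attrs["llf"] = self.llf
        df.attrs["converged"] = self.converged
        return df


class NBGLMResults(NBResultsBase):
    pass


class NBGLM:
    """Negative-binomial GLM with log link.

    Parameters
    ----------
    y : array of non-negative integer counts
    X : design matrix (n x k), must be full rank
    exog_names : optional column names for reporting
    """

    def __init__(self, y, X, exog_names=None):
        self.y, self.X = _validate_design(y, X)
        k = self.X.shape[1]
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{i}" for i in range(k)
        ]

    @classmethod
    def from_formula_frame(cls, frame: pd.DataFrame, response: str, covariate: str):
        """Build ``response ~ 1 + covariate`` from a tidy DataFrame."""
        y = frame[response].to_numpy()
        x = frame[covariate].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(y)), x])
        return cls(y, X, exog_names=["Intercept", covariate])

    # -- likelihood pieces --------------------------------------------

    def loglike(self, beta, theta) -> float:
        eta = np.clip(self.X @ beta, -_ETA_CLIP, _ETA_CLIP)
        return nb_loglike(self.y, np.exp(eta), theta)

    def _irls(self, theta, beta, tol=1e-12, max_iter=100):
        """Fisher-scoring IRLS for beta at fixed theta."""
        X, y = self.X, self.y
        for _ in range(max_iter):
            eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
            mu = np.exp(eta)
            w = mu / (1.0 + mu / theta)  # expected information weights
            z = eta + (y - mu) / mu
            sw = np.sqrt(w)
            new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
            if np.max(np.abs(new - beta)) < tol * (1.0 + np.max(np.abs(beta))):
                beta = new
                break
            beta = new
        return beta

    @staticmethod
    def _theta_score(theta, y, mu):
        return np.sum(special.digamma(y + theta) - special.digamma(theta)
                      + np.log(theta) + 1.0 - np.log(theta + mu)
                      - (y + theta) / (theta + mu))

    def _update_theta(self, theta, mu, max_iter=50):
        """Newton in log(theta) on the profile score; bisection fallback."""
        y = self.y
        u = np.log(theta)
        for _ in range(max_iter):
            th = np.exp(u)
            s = self._theta_score(th, y, mu)
            curv = np.sum(special.polygamma(1, y + th) - special.polygamma(1, th)
                          + 1.0 / th - 1.0 / (th + mu)
                          + (y - mu) / (th + mu) ** 2)
            d1 = th * s
            d2 = th * th * curv + d1
            if not np.isfinite(d1) or not np.isfinite(d2) or d2 >= 0:
                step = np.sign(d1) * 0.5 if np.isfinite(d1) else 0.0
            else:
                step = -d1 / d2
            step = np.clip(step, -2.0, 2.0)
            u_new = np.clip(u + step, np.log(THETA_MIN), np.log(THETA_MAX))
            if abs(u_new - u) < 1e-12:
                u = u_new
                break
            u = u_new
        return float(np.exp(u))

    def fit(self, tol=1e-10, max_iter=100) -> NBGLMResults:
        y, X = self.y, self.X
        # Poisson start for beta; moment start for theta
        beta = np.zeros(X.shape[1])
        beta[np.argmax(np.all(X == 1.0, axis=0))] = np.log(max(y.mean(), 1e-8)) \
            if np.any(np.all(X == 1.0, axis=0)) else 0.0
        beta = self._irls(THETA_MAX, beta)  # near-Poisson IRLS start
        mu = np.exp(np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP))
        resid_var = np.mean((y - mu) ** 2)
        mbar = mu.mean()
        theta = mbar ** 2 / max(resid_var - mbar, 1e-8)
        theta = float(np.clip(theta, 0.05, 1e4))

        ll_old = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            beta = self._irls(theta, beta)
            mu = np.exp(np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP))
            theta = self._update_theta(theta, mu)
            ll = nb_loglike(y, mu, theta)
            if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
                converged = True
                break
            ll_old = ll
        ll = nb_loglike(y, mu, theta)
        boundary = theta <= THETA_MIN * (1 + 1e-6) or theta >= THETA_MAX * (1 - 1e-6)
        # observed information for beta at (beta, theta)
        w_obs = theta * mu * (theta + y) / (theta + mu) ** 2
        info = X.T @ (X * w_obs[:, None])
        try:
            cov = np.linalg.inv(info)
            bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:  # pragma: no cover - guarded by rank check
            bse = np.full(X.shape[1], np.nan)
            converged = False
        return NBGLMResults(self, beta, bse, theta, ll, converged, it,
                            theta_boundary=boundary)


class NBGLMMResults(NBResultsBase):
    def __init__(self, model, params, bse, theta, sigma_b, llf, converged,
                 n_iter, theta_boundary=False, sigma_boundary=False):
        super().__init__(model, params, bse, theta, llf, converged, n_iter,
                         theta_boundary=theta_boundary)
        self.sigma_b = float(sigma_b)
        self.sigma_boundary = bool(sigma_boundary)

    def summary(self) -> pd.DataFrame:
        df = super().summary()
        df.attrs["sigma_b"] = self.sigma_b
        df.attrs["sigma_boundary"] = self.sigma_boundary
        return df


class NBGLMM:
    """NB GLMM with a normal random intercept per group.

    The marginal likelihood integrates the host intercept out with
    adaptive Gauss-Hermite quadrature centred on each group's
    conditional mode (``n_quad=1`` gives the Laplace approximation).
    A fit driven to sigma_b = 0 is valid and flagged as a boundary fit.
    """

    def __init__(self, y, X, groups, exog_names=None, n_quad: int = 7):
        y, X = _validate_design(y, X)
        groups = np.asarray(groups)
        if len(groups) != len(y):
            raise ValueError("groups must align with y")
        if len(np.unique(groups)) < 2:
            raise ValueError("need at least 2 groups for a random intercept")
        order = np.argsort(groups, kind="mergesort")
        self.y = y[order]
        self.X = X[order]
        self.groups = groups[order]
        _, starts = np.unique(self.groups, return_index=True)
        self.group_starts = starts
        self.group_idx = np.repeat(np.arange(len(starts)),
                                   np.diff(np.append(starts, len(y))))
        self.n_groups = len(starts)
        self.n_quad = int(n_quad)
        nodes, weights = hermgauss(self.n_quad)
        self._gh_x = nodes
        self._gh_logw = np.log(weights)
        k = X.shape[1]
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{i}" for i in range(k)
        ]
        self._b_cache = np.zeros(self.n_groups)

    # -- marginal likelihood ------------------------------------------

    def _group_sum(self, v):
        return np.add.reduceat(v, self.group_starts)

    def _modes(self, eta0, theta, sigma2, b):
        """Newton maximisation of each group's conditional log-density."""
        y, idx = self.y, self.group_idx
        for _ in range(50):
            mu = np.exp(np.clip(eta0 + b[idx], -_ETA_CLIP, _ETA_CLIP))
            grad = self._group_sum(theta * (y - mu) / (theta + mu)) - b / sigma2
            hess = self._group_sum(theta * mu * (theta + y) / (theta + mu) ** 2) \
                + 1.0 / sigma2
            step = np.clip(grad / hess, -4.0, 4.0)
            b = b + step
            if np.max(np.abs(step)) < 1e-10:
                break
        mu = np.exp(np.clip(eta0 + b[idx], -_ETA_CLIP, _ETA_CLIP))
        hess = self._group_sum(theta * mu * (theta + y) / (theta + mu) ** 2) \
            + 1.0 / sigma2
        return b, hess

    def _marginal_nll(self, params):
        k = self.X.shape[1]
        beta = params[:k]
        theta = float(np.exp(params[k]))
        sigma = float(np.exp(params[k + 1]))
        sigma2 = sigma * sigma
        eta0 = self.X @ beta
        b_hat, hess = self._modes(eta0, theta, sigma2, self._b_cache.copy())
        self._b_cache = b_hat
        s = 1.0 / np.sqrt(hess)  # per-group quadrature scale
        # evaluate the joint log-density at shifted nodes b = b_hat + sqrt(2) s x
        b_nodes = b_hat[:, None] + np.sqrt(2.0) * s[:, None] * self._gh_x[None, :]
        eta = eta0[:, None] + b_nodes[self.group_idx, :]
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        ll_obs = _nb_ll_terms(self.y[:, None], mu, theta)
        f = np.add.reduceat(ll_obs, self.group_starts, axis=0)
        f += (-b_nodes ** 2 / (2.0 * sigma2)
              - np.log(sigma) - 0.5 * np.log(2.0 * np.pi))
        a = f + self._gh_x[None, :] ** 2 + self._gh_logw[None, :]
        amax = a.max(axis=1)
        ll_groups = amax + np.log(np.sum(np.exp(a - amax[:, None]), axis=1)) \
            + 0.5 * np.log(2.0) + np.log(s)
        total = float(np.sum(ll_groups))
        if not np.isfinite(total):
            return 1e10
        return -total

    def loglike(self, beta, theta, sigma_b) -> float:
        params = np.concatenate([
            np.asarray(beta, dtype=float),
            [np.log(theta), np.log(max(sigma_b, np.exp(LOG_SIGMA_MIN)))],
        ])
        return -self._marginal_nll(params)

    def fit(self, tol=1e-6, max_iter=200, start=None) -> NBGLMMResults:
        k = self.X.shape[1]
        if start is None:
            try:
                glm = NBGLM(self.y, self.X).fit()
                beta0, theta0 = glm.params, glm.theta
            except Exception:
                beta0 = np.zeros(k)
                beta0[0] = np.log(max(self.y.mean(), 1e-8))
                theta0 = 1.0
            start = np.concatenate([
                beta0, [np.log(np.clip(theta0, THETA_MIN * 2, THETA_MAX / 2)),
                        np.log(0.5)],
            ])
        bounds = [(None, None)] * k + [
            (np.log(THETA_MIN), np.log(THETA_MAX)),
            (LOG_SIGMA_MIN, LOG_SIGMA_MAX),
        ]
        self._b_cache = np.zeros(self.n_groups)
        res = optimize.minimize(
            self._marginal_nll, start, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol * 1e-3, "gtol": 1e-6},
        )
        params = res.x
        beta = params[:k]
        theta = float(np.exp(params[k]))
        sigma = float(np.exp(params[k + 1]))
        sigma_boundary = params[k + 1] <= LOG_SIGMA_MIN + 1e-3
        theta_boundary = (params[k] <= np.log(THETA_MIN) + 1e-6
                          or params[k] >= np.log(THETA_MAX) - 1e-6)
        llf = -res.fun
        bse = self._bse(params, sigma_boundary, theta_boundary, k)
        sigma_out = 0.0 if sigma_boundary else sigma
        return NBGLMMResults(self, beta, bse, theta, sigma_out, llf,
                             res.success, res.nit,
                             theta_boundary=theta_boundary,
                             sigma_boundary=sigma_boundary)

    def _bse(self, params, sigma_boundary, theta_boundary, k):
        """SEs from a finite-difference observed information, holding any
        boundary variance parameters fixed."""
        free = list(range(k + 2))
        if sigma_boundary:
            free.remove(k + 1)
        if theta_boundary:
            free.remove(k)
        nf = len(free)
        h = 1e-4 * (1.0 + np.abs(params[free]))
        H = np.zeros((nf, nf))
        f0 = self._marginal_nll(params)

        def feval(delta):
            p = params.copy()
            p[free] = p[free] + delta
            return self._marginal_nll(p)

        for a in range(nf):
            ea = np.zeros(nf); ea[a] = h[a]
            fpp = feval(ea); fmm = feval(-ea)
            H[a, a] = (fpp - 2.0 * f0 + fmm) / (h[a] ** 2)
            for b in range(a + 1, nf):
                eb = np.zeros(nf); eb[b] = h[b]
                fab = feval(ea + eb)
                fa_b = feval(ea - eb)
                f_ab = feval(-ea + eb)
                f_a_b = feval(-ea - eb)
                H[a, b] = H[b, a] = (fab - fa_b - f_ab + f_a_b) / (4 * h[a] * h[b])
        bse = np.full(k + 2, np.nan)
        try:
            cov = np.linalg.inv(H)
            diag = np.clip(np.diag(cov), 0, None)
            for i, idx in enumerate(free):
                bse[idx] = np.sqrt(diag[i])
        except np.linalg.LinAlgError:
            pass
        return bse[:k]
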