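"""Cluster-specific analysis: random-intercept logistic regression.

Model: logit Pr(y_jl = 1) = x_jl' beta_conditional + U_j with cluster effects
U_j ~ N(0, sigma_B^2).  The marginal likelihood integrates the random
intercept out of each cluster's Bernoulli likelihood; the integral is
evaluated by adaptive Gauss-Hermite quadrature centered and scaled at each
cluster's conditional mode, and maximized by quasi-Newton (BFGS) over
(beta, log sigma_B).  Standard errors come from the inverse of a numerical
observed-information matrix on the natural (beta, sigma_B^2) scale.

The between-cluster variance is parametrized as log sigma_B during
optimization so it can never go negative; fits whose variance collapses to
the boundary (sigma_B^2 < 1e-8) are flagged, mirroring the failures that
unconstrained mixed-model software reports as negative variance estimates.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .gee import wald_interval

__all__ = ["RandomInterceptLogit", "fit_relr", "relr_loglik"]

_LOG_2PI = np.log(2.0 * np.pi)


class _ClusterLik:
    """Per-cluster Bernoulli log-likelihood log f(y_j | u) and u-derivatives.

    Uses sufficient statistics (cluster size, success count) when the linear
    predictor is constant within every cluster (intercept + cluster-level
    covariates, the trial analysis model); falls back to subject-level sums
    otherwise.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, clusters: np.ndarray):
        order = np.argsort(clusters, kind="stable")
        self.X = X[order]
        self.y = y[order]
        _, self.starts, counts = np.unique(
            clusters[order], return_index=True, return_counts=True
        )
        self.m = counts.astype(float)
        self.G = len(self.starts)
        # cluster-constant design? (every column constant within cluster)
        first = np.repeat(self.X[self.starts], counts, axis=0)
        self.constant = bool(np.all(self.X == first))
        self.Xc = self.X[self.starts]  # representative row per cluster
        self.s = np.add.reduceat(self.y, self.starts)

    def set_beta(self, beta: np.ndarray) -> None:
        self.eta = self.X @ beta          # per subject
        self.eta_c = self.Xc @ beta       # per cluster (constant case)

    def logf(self, u: np.ndarray) -> np.ndarray:
        """log f(y_j | u_j) for one offset per cluster; u shape (G,)."""
        if self.constant:
            t = self.eta_c + u
            return self.s * t - self.m * np.logaddexp(0.0, t)
        t = self.eta + u.repeat(self.m.astype(int))
        contrib = self.y * t - np.logaddexp(0.0, t)
        return np.add.reduceat(contrib, self.starts)

    def dlogf(self, u: np.ndarray) -> np.ndarray:
        if self.constant:
            return self.s - self.m * special.expit(self.eta_c + u)
        t = self.eta + u.repeat(self.m.astype(int))
        return self.s - np.add.reduceat(special.expit(t), self.starts)

    def d2logf(self, u: np.ndarray) -> np.ndarray:
        if self.constant:
            p = special.expit(self.eta_c + u)
            return -self.m * p * (1.0 - p)
        t = self.eta + u.repeat(self.m.astype(int))
        p = special.expit(t)
        return -np.add.reduceat(p * (1.0 - p), self.starts)

    def logf_nodes(self, U: np.ndarray) -> np.ndarray:
        """log f(y_j | u) on a (G, K) grid of offsets."""
        if self.constant:
            t = self.eta_c[:, None] + U
            return self.s[:, None] * t - self.m[:, None] * np.logaddexp(0.0, t)
        t = self.eta[:, None] + U.repeat(self.m.astype(int), axis=0)
        contrib = self.y[:, None] * t - np.logaddexp(0.0, t)
        return np.add.reduceat(contrib, self.starts, axis=0)


def _agq_cluster_logliks(
    lik: _ClusterLik, sigma_b: float, n_quad: int
) -> np.ndarray:
    """Adaptive Gauss-Hermite log integral per cluster.

    Centers nodes at each cluster's conditional mode u_hat of
    h(u) = log f(y|u) - u^2/(2 sigma^2) and scales by 1/sqrt(-h''(u_hat)).
    """
    sig2 = sigma_b * sigma_b
    u = np.zeros(lik.G)
    for _ in range(100):  # Newton on the concave h(u)
        g = lik.dlogf(u) - u / sig2
        H = lik.d2logf(u) - 1.0 / sig2
        step = g / H
        u = u - step
        if np.abs(step).max() < 1e-10:
            break
    tau = 1.0 / np.sqrt(-(lik.d2logf(u) - 1.0 / sig2))

    z, w = np.polynomial.hermite.hermgauss(n_quad)
    U = u[:, None] + np.sqrt(2.0) * tau[:, None] * z[None, :]
    h = (
        lik.logf_nodes(U)
        - U * U / (2.0 * sig2)
        - np.log(sigma_b)
        - 0.5 * _LOG_2PI
    )
    return (
        logsumexp(h + z[None, :] ** 2 + np.log(w)[None, :], axis=1)
        + 0.5 * np.log(2.0)
        + np.log(tau)
    )


def relr_loglik(
    beta, sigma_b: float, X, y, clusters, n_quad: int = 21
) -> float:
    """Marginal log-likelihood of the random-intercept logistic model.

    Sum over clusters of log integral of the cluster Bernoulli likelihood
    against the N(0, sigma_b^2) random-effect density, by adaptive
    Gauss-Hermite quadrature.  ``sigma_b = 0`` returns the ordinary logistic
    log-likelihood exactly.
    """
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    Xd = np.column_stack([np.ones(len(X)), X])
    y = np.asarray(y, float)
    lik = _ClusterLik(Xd, y, np.asarray(clusters))
    lik.set_beta(np.asarray(beta, float))
    if sigma_b == 0.0:
        return float(lik.logf(np.zeros(lik.G)).sum())
    return float(_agq_cluster_logliks(lik, float(sigma_b), n_quad).sum())


class RandomInterceptLogit(BaseEstimator):
    """ML random-intercept logistic regression via adaptive quadrature.

    Parameters
    ----------
    n_quad : int, default 21
        Number of adaptive Gauss-Hermite nodes per cluster.
    boundary_tol : float
        The fit is flagged ``boundary_`` when sigma_B^2 falls below this.

    Attributes
    ----------
    params_ : ndarray, coefficients (intercept first).
    se_ : ndarray, Wald SEs from the inverse observed information.
    sigma_b2_ : float, between-cluster variance estimate.
    loglik_ : float
    converged_ : bool  (optimizer success and invertible information)
    boundary_ : bool
    """

    def __init__(
        self,
        n_quad: int = 21,
        max_iter: int = 200,
        boundary_tol: float = 1e-8,
    ):
        self.n_quad = n_quad
        self.max_iter = max_iter
        self.boundary_tol = boundary_tol

    def _nll_factory(self, lik: _ClusterLik):
        def nll(theta: np.ndarray) -> float:
            lik.set_beta(theta[:-1])
            sigma = np.exp(theta[-1])
            return -float(_agq_cluster_logliks(lik, sigma, self.n_quad).sum())

        return nll

    def fit(self, X, y, clusters):
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, float)
        clusters = np.asarray(clusters)
        if np.isnan(y).any():
            raise ValueError("missing outcomes must be removed before fitting")
        if y.min() == y.max():
            raise ValueError("outcome is constant; both 0 and 1 are required")
        Xd = np.column_stack([np.ones(len(y)), X])
        p = Xd.shape[1]
        lik = _ClusterLik(Xd, y, clusters)

        beta0 = self._start_beta(Xd, y)
        logsig0 = self._start_logsigma(lik, beta0)
        nll = self._nll_factory(lik)
        res = optimize.minimize(
            nll,
            np.concatenate([beta0, [logsig0]]),
            method="BFGS",
            options={"maxiter": self.max_iter, "gtol": 1e-5},
        )
        theta = res.x
        self.n_iter_ = int(res.nit)
        self.params_ = theta[:-1].copy()
        sigma = float(np.exp(theta[-1]))
        self.sigma_b2_ = sigma * sigma
        self.loglik_ = -float(res.fun)
        self.boundary_ = self.sigma_b2_ < self.boundary_tol
        ok = bool(np.all(np.isfinite(theta))) and np.isfinite(res.fun)

        self.se_ = np.full(p, np.nan)
        self.cov_ = np.full((p + 1, p + 1), np.nan)
        if ok and not self.boundary_:
            cov = self._observed_information_inverse(lik, nll)
            if cov is not None:
                self.cov_ = cov
                self.se_ = np.sqrt(np.diag(cov)[:p])
            else:
                ok = False
        self.converged_ = ok and (res.success or np.abs(res.jac).max() < 1e-3)
        return self

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _start_beta(Xd: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Moment start: shrunken logit of the mean, slopes from least squares
        on working logits (adequate as a quasi-Newton starting point)."""
        p = Xd.shape[1]
        beta = np.zeros(p)
        ybar = np.clip(y.mean(), 1e-3, 1 - 1e-3)
        beta[0] = special.logit(ybar)
        if p > 1:
            # one IRLS step from the intercept-only start
            mu = np.full(len(y), ybar)
            w = mu * (1 - mu)
            z = special.logit(ybar) + (y - mu) / w
            XtW = Xd.T * w
            try:
                beta = np.linalg.solve(XtW @ Xd, XtW @ z)
            except np.linalg.LinAlgError:
                pass
        return beta

    @staticmethod
    def _start_logsigma(lik: _ClusterLik, beta: np.ndarray) -> float:
        """Crude variance start from cluster-level empirical logits."""
        shrunk = (lik.s + 0.5) / (lik.m + 1.0)
        lo = special.logit(shrunk)
        fitted = lik.Xc @ beta
        resid_var = float(np.var(lo - fitted, ddof=1)) if lik.G > 1 else 0.1
        samp_var = float(np.mean(1.0 / (lik.m * shrunk * (1.0 - shrunk))))
        return 0.5 * np.log(max(resid_var - samp_var, 0.01))

    def _observed_information_inverse(self, lik, nll):
        """Inverse numerical Hessian of -loglik on the (beta, sigma_B^2) scale."""
        beta = self.params_
        s2 = self.sigma_b2_

        def nll_nat(phi: np.ndarray) -> float:
            if phi[-1] <= 0:
                return np.inf
            theta = np.concatenate([phi[:-1], [0.5 * np.log(phi[-1])]])
            return nll(theta)

        phi0 = np.concatenate([beta, [s2]])
        k = len(phi0)
        h = 1e-4 * np.maximum(1.0, np.abs(phi0))
        h[-1] = min(h[-1], s2 / 2.0)
        H = np.empty((k, k))
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k)
                ej = np.zeros(k)
                ei[i] = h[i]
                ej[j] = h[j]
                fpp = nll_nat(phi0 + ei + ej)
                fpm = nll_nat(phi0 + ei - ej)
                fmp = nll_nat(phi0 - ei + ej)
                fmm = nll_nat(phi0 - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        if not np.all(np.isfinite(H)):
            return None
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return None
        if np.any(np.diag(cov)[: k - 1] <= 0):
            return None
        return cov

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """Wald z intervals for the coefficients."""
        return np.array(
            [wald_interval(b, s, level) for b, s in zip(self.params_, self.se_)]
        )


def fit_relr(data, **kwargs) -> RandomInterceptLogit:
    """Fit the intercept + treatment random-intercept model to a trial DataFrame."""
    return RandomInterceptLogit(**kwargs).fit(
        data["arm"].to_numpy(float),
        data["outcome"].to_numpy(float),
        data["cluster_id"].to_numpy(),
    )
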