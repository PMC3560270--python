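"""Marginal (population-averaged) logistic analysis by GEE.

Fits logit(Pr(y=1)) = X beta_marginal by generalized estimating equations
with an exchangeable working correlation, and reports the robust (sandwich)
standard error of each coefficient multiplied by the small-sample correction
sqrt(J/(J-1)), where J is the number of clusters per arm.  The plug-in
sandwich is biased downward by roughly (J-1)/J with few clusters, which this
factor undoes on the variance scale.

The exchangeable inverse correlation is applied in closed form,

    R^{-1} = 1/(1-alpha) * (I - alpha/(1 + (m-1) alpha) * J_m),

so no per-cluster matrix is ever materialized; all cluster sums are grouped
``np.add.reduceat`` reductions.  The working correlation alpha is refreshed
every Fisher-scoring step from the moment estimator on standardized Pearson
residual cross-products with denominator sum_j m_j (m_j - 1)/2 - p.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special, stats
from sklearn.base import BaseEstimator

__all__ = ["ExchangeableGEE", "fit_gee", "small_sample_factor", "wald_interval"]


def small_sample_factor(J: float) -> float:
    """Multiplicative small-sample correction for the sandwich SE.

    ``sqrt(J / (J - 1))`` with J the number of clusters in each arm;
    equivalently J/(J-1) on the variance.  Vanishes (-> 1) as J grows.
    """
    if J < 2:
        raise ValueError("small-sample correction requires J >= 2 clusters per arm")
    return math.sqrt(J / (J - 1.0))


def wald_interval(estimate: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Normal-quantile Wald confidence interval (non-MI analyses)."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    return estimate - z * se, estimate + z * se


class ExchangeableGEE(BaseEstimator):
    """Logistic GEE with exchangeable working correlation and corrected sandwich SEs.

    Parameters
    ----------
    small_sample : bool, default True
        Multiply sandwich SEs by sqrt(J/(J-1)) with J = clusters per arm
        (inferred as half the number of clusters in the balanced two-arm
        design unless ``clusters_per_arm`` is given).
    fix_alpha : float or None
        If set, the working correlation is held at this value instead of
        being estimated (``fix_alpha=0`` reproduces ordinary logistic
        regression estimates).
    tol : float
        Convergence threshold on the max absolute coefficient update.

    Attributes
    ----------
    params_ : ndarray of shape (p+1,)
        Coefficients, intercept first.
    robust_se_ : ndarray
        Corrected sandwich SEs (equal to ``robust_se_uncorrected_`` when
        ``small_sample=False``).
    working_alpha_ : float
    converged_ : bool
    n_iter_ : int
    """

    def __init__(
        self,
        small_sample: bool = True,
        fix_alpha: float | None = None,
        clusters_per_arm: int | None = None,
        max_iter: int = 100,
        tol: float = 1e-6,
    ):
        self.small_sample = small_sample
        self.fix_alpha = fix_alpha
        self.clusters_per_arm = clusters_per_arm
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y, clusters):
        """Fit the marginal model.

        Parameters
        ----------
        X : array-like of shape (n,) or (n, p)
            Covariates without intercept (the treatment indicator in the
            trial analyses).
        y : array-like of shape (n,)
            Binary outcomes, no missing values.
        clusters : array-like of shape (n,)
            Cluster labels defining the independence blocks.
        """
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, float)
        clusters = np.asarray(clusters)
        if np.isnan(y).any():
            raise ValueError("missing outcomes must be removed before fitting")
        if y.min() == y.max():
            raise ValueError("outcome is constant; both 0 and 1 are required")

        order = np.argsort(clusters, kind="stable")
        Xs, ys = X[order], y[order]
        _, starts, counts = np.unique(
            clusters[order], return_index=True, return_counts=True
        )
        G = len(starts)
        if G < 4:
            raise ValueError("need at least 2 clusters per arm")
        m = counts.astype(float)
        Xd = np.column_stack([np.ones(len(ys)), Xs])
        p = Xd.shape[1]

        pair_den = (m * (m - 1.0)).sum() / 2.0 - p

        beta = np.zeros(p)
        beta[0] = special.logit(np.clip(ys.mean(), 1e-6, 1 - 1e-6))
        alpha = 0.0 if self.fix_alpha is None else float(self.fix_alpha)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            eta = Xd @ beta
            mu = special.expit(eta)
            mu = np.clip(mu, 1e-10, 1 - 1e-10)
            A = mu * (1.0 - mu)
            a = np.sqrt(A)
            resid = ys - mu
            r = resid / a

            S = np.add.reduceat(r, starts)
            if self.fix_alpha is None:
                Q = np.add.reduceat(r * r, starts)
                num = ((S * S - Q) / 2.0).sum()
                alpha = num / pair_den if pair_den > 0 else 0.0
                lo = -1.0 / (m.max() - 1.0) + 1e-6 if m.max() > 1 else -0.99
                alpha = float(np.clip(alpha, lo, 1 - 1e-6))

            c1 = 1.0 / (1.0 - alpha)
            c2 = alpha / (1.0 + (m - 1.0) * alpha)  # per cluster

            V = Xd * a[:, None]
            Tv = np.add.reduceat(V, starts, axis=0)  # sum_l a x  (G, p)
            XAX = (Xd * A[:, None]).T @ Xd
            bread = c1 * (XAX - np.einsum("j,ja,jb->ab", c2, Tv, Tv))
            Xr = np.add.reduceat(Xd * resid[:, None], starts, axis=0)
            g = c1 * (Xr - c2[:, None] * Tv * S[:, None])  # per-cluster scores
            score = g.sum(axis=0)

            try:
                delta = np.linalg.solve(bread, score)
            except np.linalg.LinAlgError:
                break
            beta = beta + delta
            if not np.all(np.isfinite(beta)) or np.abs(beta).max() > 30:
                break
            if np.abs(delta).max() < self.tol:
                converged = True
                break

        self.n_iter_ = it
        self.working_alpha_ = alpha
        self.params_ = beta
        self.converged_ = bool(converged)
        if not converged:
            self.robust_se_ = np.full(p, np.nan)
            self.robust_se_uncorrected_ = np.full(p, np.nan)
            self.cov_ = np.full((p, p), np.nan)
            return self

        # Sandwich at the solution: bread^{-1} (sum_j g_j g_j') bread^{-1}
        eta = Xd @ beta
        mu = np.clip(special.expit(eta), 1e-10, 1 - 1e-10)
        A = mu * (1.0 - mu)
        a = np.sqrt(A)
        resid = ys - mu
        c1 = 1.0 / (1.0 - alpha)
        c2 = alpha / (1.0 + (m - 1.0) * alpha)
        V = Xd * a[:, None]
        Tv = np.add.reduceat(V, starts, axis=0)
        XAX = (Xd * A[:, None]).T @ Xd
        bread = c1 * (XAX - np.einsum("j,ja,jb->ab", c2, Tv, Tv))
        S = np.add.reduceat(resid / a, starts)
        Xr = np.add.reduceat(Xd * resid[:, None], starts, axis=0)
        g = c1 * (Xr - c2[:, None] * Tv * S[:, None])
        meat = g.T @ g
        bread_inv = np.linalg.inv(bread)
        cov = bread_inv @ meat @ bread_inv
        se = np.sqrt(np.diag(cov))
        self.robust_se_uncorrected_ = se
        if self.small_sample:
            J = self.clusters_per_arm if self.clusters_per_arm is not None else G / 2.0
            factor = small_sample_factor(J)
            self.cov_ = cov * factor**2
            self.robust_se_ = se * factor
        else:
            self.cov_ = cov
            self.robust_se_ = se.copy()
        return self

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """Wald z intervals for all coefficients, rows (lower, upper)."""
        return np.array(
            [wald_interval(b, s, level) for b, s in zip(self.params_, self.robust_se_)]
        )


def fit_gee(data, **kwargs) -> ExchangeableGEE:
    """Fit the intercept + treatment GEE model to a trial DataFrame.

    ``data`` must carry columns ``arm``, ``outcome``, ``cluster_id`` with no
    missing outcomes (the missing-data strategy runs first).
    """
    return ExchangeableGEE(**kwargs).fit(
        data["arm"].to_numpy(float),
        data["outcome"].to_numpy(float),
        data["cluster_id"].to_numpy(),
    )
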