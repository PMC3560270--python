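"""Independent brute-force implementations used only as test oracles.

Everything here deliberately trades efficiency for transparency: dense
per-cluster matrices with explicit inverses for the GEE sandwich, a fine
trapezoid grid for the mixed-model integral, and exact-rational evaluation of
the pooling formulas.  None of it shares code with the package's optimized
paths.
"""

from __future__ import annotations

import numpy as np
import sympy
from scipy import optimize, special


def dense_gee_fit(X, y, clusters, max_iter=100, tol=1e-6):
    """Dense-matrix exchangeable logistic GEE.

    Builds each cluster's working covariance V_j = A^{1/2} R A^{1/2}
    explicitly and inverts it with np.linalg.inv; returns
    (beta, uncorrected sandwich covariance, alpha).
    """
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    Xd = np.column_stack([np.ones(len(X)), X])
    y = np.asarray(y, float)
    labels = np.unique(clusters)
    idx = [np.where(clusters == g)[0] for g in labels]
    p = Xd.shape[1]
    pair_den = sum(len(i) * (len(i) - 1) / 2 for i in idx) - p

    beta = np.zeros(p)
    beta[0] = special.logit(y.mean())
    alpha = 0.0
    for _ in range(max_iter):
        mu = special.expit(Xd @ beta)
        r = (y - mu) / np.sqrt(mu * (1 - mu))
        num = 0.0
        for i in idx:
            ri = r[i]
            num += (ri.sum() ** 2 - (ri**2).sum()) / 2.0
        alpha = num / pair_den if pair_den > 0 else 0.0

        H = np.zeros((p, p))
        s = np.zeros(p)
        for i in idx:
            m = len(i)
            A = np.diag(mu[i] * (1 - mu[i]))
            R = np.full((m, m), alpha) + (1 - alpha) * np.eye(m)
            V = np.sqrt(A) @ R @ np.sqrt(A)
            Vinv = np.linalg.inv(V)
            D = A @ Xd[i]
            H += D.T @ Vinv @ D
            s += D.T @ Vinv @ (y[i] - mu[i])
        delta = np.linalg.solve(H, s)
        beta = beta + delta
        if np.abs(delta).max() < tol:
            break

    mu = special.expit(Xd @ beta)
    H = np.zeros((p, p))
    meat = np.zeros((p, p))
    for i in idx:
        m = len(i)
        A = np.diag(mu[i] * (1 - mu[i]))
        R = np.full((m, m), alpha) + (1 - alpha) * np.eye(m)
        Vinv = np.linalg.inv(np.sqrt(A) @ R @ np.sqrt(A))
        D = A @ Xd[i]
        H += D.T @ Vinv @ D
        g = D.T @ Vinv @ (y[i] - mu[i])
        meat += np.outer(g, g)
    Hinv = np.linalg.inv(H)
    return beta, Hinv @ meat @ Hinv, alpha


def trapezoid_relr_loglik(beta, sigma_b, X, y, clusters, lo=-10.0, hi=10.0, n=10001):
    """Random-intercept logistic log-likelihood by dense trapezoid integration."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    Xd = np.column_stack([np.ones(len(X)), X])
    eta = Xd @ np.asarray(beta, float)
    y = np.asarray(y, float)
    u = np.linspace(lo, hi, n)
    phi = np.exp(-(u**2) / (2 * sigma_b**2)) / (sigma_b * np.sqrt(2 * np.pi))
    total = 0.0
    for g in np.unique(clusters):
        i = np.where(clusters == g)[0]
        t = eta[i][:, None] + u[None, :]
        logf = (y[i][:, None] * t - np.logaddexp(0.0, t)).sum(axis=0)
        total += np.log(np.trapezoid(np.exp(logf) * phi, u))
    return float(total)


def brute_force_fit_relr(X, y, clusters):
    """ML fit maximizing the trapezoid log-likelihood (independent of AGQ)."""

    def nll(theta):
        return -trapezoid_relr_loglik(
            theta[:-1], np.exp(theta[-1]), X, y, clusters, n=4001
        )

    best = None
    for logsig0 in (-1.0, 0.0):
        res = optimize.minimize(
            nll, np.array([0.0, 0.0, logsig0]), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x[:-1], np.exp(2 * best.x[-1]), -best.fun


def barnard_rubin_exact(W, B, M, k):
    """Exact-rational evaluation of the adjusted degrees of freedom."""
    Wr, Br, Mr = sympy.Rational(W), sympy.Rational(B), sympy.Integer(M)
    V = Wr + (1 + sympy.Rational(1, M)) * Br
    nu_com = sympy.Integer(2 * (k - 1))
    gamma = (1 + sympy.Rational(1, M)) * Br / V
    nu_obs = (nu_com + 1) / (nu_com + 3) * nu_com * (1 - gamma)
    if B == 0:
        return float(nu_obs)
    nu_M = (Mr - 1) * (1 + Mr / (Mr + 1) * Wr / Br) ** 2
    return float(1 / (1 / nu_M + 1 / nu_obs))
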