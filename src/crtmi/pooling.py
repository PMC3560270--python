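"""Rubin's rules with the Barnard-Rubin small-sample degrees of freedom.

Given M per-imputation estimates beta_m with variances V_m, the pooled
estimate is their mean; the pooled variance is V = W + (1 + 1/M) B with W the
mean within-imputation variance and B the between-imputation variance.  The
t reference uses the Barnard-Rubin adjusted degrees of freedom

    1/nu_adj = 1/nu_M + 1/nu_obs,
    nu_M   = (M - 1) [1 + (M/(M+1)) W/B]^2,
    nu_obs = ((nu_com + 1)/(nu_com + 3)) nu_com (1 - gamma),

with gamma = (1 + 1/M) B / V and nu_com the complete-data degrees of freedom,
which for a balanced CRT with k clusters per arm is 2(k - 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PooledEstimate", "rubin_pool"]


@dataclass(frozen=True)
class PooledEstimate:
    beta_bar: float
    within_var: float
    between_var: float
    total_var: float
    df_adjusted: float
    ci: tuple[float, float]


def rubin_pool(
    estimates,
    variances,
    clusters_per_arm: int,
    level: float = 0.95,
) -> PooledEstimate:
    """Pool M complete-data analyses of multiply imputed datasets.

    Parameters
    ----------
    estimates, variances : array-like of length M >= 2
        Per-imputation treatment-effect estimates and squared SEs.
    clusters_per_arm : int
        k > 2; sets the complete-data degrees of freedom nu_com = 2(k-1).
    level : float
        Nominal confidence level of the pooled t interval.
    """
    est = np.asarray(estimates, float)
    var = np.asarray(variances, float)
    M = len(est)
    if M < 2 or len(var) != M:
        raise ValueError("need M >= 2 estimates with matching variances")
    if np.any(var <= 0):
        raise ValueError("variances must be positive")
    if clusters_per_arm <= 2:
        raise ValueError("clusters_per_arm must exceed 2")

    beta_bar = est.mean()
    W = var.mean()
    B = ((est - beta_bar) ** 2).sum() / (M - 1)
    V = W + (1.0 + 1.0 / M) * B

    nu_com = 2.0 * (clusters_per_arm - 1)
    gamma = (1.0 + 1.0 / M) * B / V
    nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - gamma)
    if B == 0.0:
        nu_adj = nu_obs
    else:
        nu_M = (M - 1.0) * (1.0 + (M / (M + 1.0)) * W / B) ** 2
        nu_adj = 1.0 / (1.0 / nu_M + 1.0 / nu_obs)

    half = stats.t.ppf(0.5 + level / 2.0, nu_adj) * np.sqrt(V)
    return PooledEstimate(
        beta_bar=float(beta_bar),
        within_var=float(W),
        between_var=float(B),
        total_var=float(V),
        df_adjusted=float(nu_adj),
        ci=(float(beta_bar - half), float(beta_bar + half)),
    )
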