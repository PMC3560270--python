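"""Synthetic clustered binary trial data.

Outcomes are generated by a beta-binomial mechanism: each cluster draws a
success probability from a Beta distribution whose mean equals the arm
prevalence and whose dispersion induces the requested intracluster
correlation; subjects within the cluster are then i.i.d. Bernoulli given that
probability.  An auxiliary Bernoulli(0.5) covariate, independent of arm and
outcome, drives the covariate-dependent missingness mechanism.

Data live in a long-format :class:`pandas.DataFrame` with columns
``cluster_id`` (int), ``arm`` (0 control / 1 intervention), ``covariate``
(0/1) and ``outcome`` (0.0/1.0, NaN when missing).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import MissingnessSpec, TrialDesign

__all__ = [
    "beta_params",
    "generate_trial",
    "impose_cdm",
    "anova_icc",
    "read_trial_csv",
    "write_trial_csv",
]

COLUMNS = ["cluster_id", "arm", "covariate", "outcome"]


def beta_params(prevalence: float, icc: float) -> tuple[float, float]:
    """Beta parameters matching a target mean and intracluster correlation.

    With cluster probabilities P ~ Beta(alpha, beta) and outcomes Bernoulli(P)
    within a cluster, the pairwise within-cluster outcome correlation equals
    1 / (alpha + beta + 1).  Moment matching to mean = prevalence and
    correlation = icc gives ``alpha + beta = (1 - icc) / icc``, hence

        alpha = prevalence * (1 - icc) / icc
        beta  = (1 - prevalence) * (1 - icc) / icc

    The degenerate no-clustering case icc = 0 (a point mass at ``prevalence``)
    must be handled by the caller, not here.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    if not 0.0 < icc < 1.0:
        raise ValueError(
            "icc must lie in (0, 1); icc = 0 is the degenerate Bernoulli case"
        )
    total = (1.0 - icc) / icc
    return prevalence * total, (1.0 - prevalence) * total


def generate_trial(design: TrialDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Generate one complete trial (no missing outcomes).

    Clusters ``0 .. clusters_per_arm-1`` form the control arm and the next
    ``clusters_per_arm`` clusters the intervention arm.  Each cluster's
    success probability is drawn from ``Beta(beta_params(prevalence, icc))``
    (or fixed at the arm prevalence when icc = 0); subject outcomes are
    conditionally independent Bernoulli.  The auxiliary covariate is i.i.d.
    Bernoulli(0.5), independent of everything else.
    """
    k, m = design.clusters_per_arm, design.cluster_size
    n_clusters = 2 * k
    arms = np.repeat([0, 1], k)
    prev = np.where(
        arms == 0, design.prevalence_control, design.prevalence_intervention
    )

    if design.icc == 0.0:
        p_cluster = prev.astype(float)
    else:
        p_cluster = np.empty(n_clusters)
        for arm_value in (0, 1):
            mask = arms == arm_value
            a, b = beta_params(prev[mask][0], design.icc)
            p_cluster[mask] = rng.beta(a, b, size=mask.sum())

    outcome = (
        rng.random((n_clusters, m)) < p_cluster[:, None]
    ).astype(float).ravel()
    covariate = rng.integers(0, 2, size=n_clusters * m)

    return pd.DataFrame(
        {
            "cluster_id": np.repeat(np.arange(n_clusters), m),
            "arm": np.repeat(arms, m),
            "covariate": covariate,
            "outcome": outcome,
        }
    )


def impose_cdm(
    data: pd.DataFrame, spec: MissingnessSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Set outcomes to missing by the covariate-dependent mechanism.

    Each subject's outcome is independently deleted with probability
    ``spec.p0`` when ``covariate == 0`` and ``spec.p1`` when ``covariate == 1``;
    arm and covariate are never missing.  Returns a copy.
    """
    if data["outcome"].isna().any():
        raise ValueError("input data must be complete")
    out = data.copy()
    if spec.target_rate == 0.0:
        return out
    p_miss = np.where(out["covariate"].to_numpy() == 1, spec.p1, spec.p0)
    missing = rng.random(len(out)) < p_miss
    out.loc[missing, "outcome"] = np.nan
    return out


def anova_icc(data: pd.DataFrame) -> float:
    """One-way ANOVA estimate of the outcome ICC, pooled over arms.

    Standard mean-squares estimator on the 0/1 outcomes with arm as a fixed
    stratum: rho_hat = (MSB - MSW) / (MSB + (m0 - 1) MSW) where m0 is the
    (here common) cluster size.  Used by the generator's moment-recovery
    checks; may be negative by sampling error.
    """
    d = data.dropna(subset=["outcome"])
    y = d["outcome"].to_numpy(float)
    ssb = 0.0
    ssw = 0.0
    n_clusters = 0
    n_total = 0
    sizes = []
    for _, arm_df in d.groupby("arm"):
        ya = arm_df["outcome"].to_numpy(float)
        arm_mean = ya.mean()
        for _, cl in arm_df.groupby("cluster_id"):
            yc = cl["outcome"].to_numpy(float)
            ssb += len(yc) * (yc.mean() - arm_mean) ** 2
            ssw += ((yc - yc.mean()) ** 2).sum()
            sizes.append(len(yc))
            n_clusters += 1
        n_total += len(ya)
    n_arms = d["arm"].nunique()
    msb = ssb / (n_clusters - n_arms)
    msw = ssw / (n_total - n_clusters)
    sizes = np.asarray(sizes, float)
    m0 = (n_total - (sizes**2).sum() / n_total) / (n_clusters - n_arms)
    return (msb - msw) / (msb + (m0 - 1.0) * msw)


def write_trial_csv(data: pd.DataFrame, path) -> None:
    """Write subject-level records; missing outcomes become empty fields."""
    data.to_csv(path, index=False, columns=COLUMNS)


def read_trial_csv(path) -> pd.DataFrame:
    """Read subject-level records written by :func:`write_trial_csv`."""
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV missing columns: {missing}")
    df["cluster_id"] = df["cluster_id"].astype(int)
    df["arm"] = df["arm"].astype(int)
    df["covariate"] = df["covariate"].astype(int)
    df["outcome"] = df["outcome"].astype(float)
    return df[COLUMNS]
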