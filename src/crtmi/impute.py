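"""Missing-outcome strategies: complete case, standard MI, within-cluster MI.

Standard multiple imputation follows the four-step posterior-draw recipe for
a binary outcome: (1) fit a logistic regression of the observed outcomes on
the covariates (treatment arm and the auxiliary covariate associated with the
missingness), giving estimates beta_hat and covariance V; (2) draw
beta_tilde = beta_hat + L Z where L L' = V is a Cholesky factor and Z is
standard normal; (3) compute each missing subject's success probability
expit(x' beta_tilde); (4) impute by comparing a uniform draw with that
probability.  Subjects are treated as independent, i.e. the imputation model
deliberately ignores clustering.

Within-cluster MI applies the same recipe separately inside each cluster, so
only that cluster's observed outcomes inform its imputations.  The treatment
indicator is constant within a cluster and is dropped from the model.  With
small clusters the per-cluster model frequently cannot be fit (no observed
outcomes, or all observed outcomes identical); the whole strategy is then
flagged inapplicable for that dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special
from sklearn.base import BaseEstimator

__all__ = [
    "ImputationError",
    "ImputationModel",
    "ImputedSet",
    "complete_case",
    "PosteriorDrawImputer",
    "WithinClusterImputer",
    "posterior_draw_imputer",
    "within_cluster_mi",
    "write_imputed_set",
]

_SEPARATION_BOUND = 15.0  # |coef| beyond this is treated as (near-)separation


class ImputationError(RuntimeError):
    """The imputation model could not be fit for this dataset."""


@dataclass(frozen=True)
class ImputationModel:
    """Fitted logistic imputation model: coefficients and their covariance."""

    coef_hat: np.ndarray
    covariance: np.ndarray
    covariate_names: tuple[str, ...]

    def draw_coefficients(
        self, rng: np.random.Generator, ridge: float = 1e-6
    ) -> np.ndarray:
        """One posterior draw beta_tilde = beta_hat + L Z, with L L' = V.

        A small ridge (relative to the mean diagonal) is added only if the
        Cholesky factorization fails on a numerically semidefinite V.
        """
        V = self.covariance
        if not V.any():  # degenerate posterior: point mass at beta_hat
            return self.coef_hat.copy()
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            jitter = ridge * max(np.trace(V) / len(V), 1.0)
            L = np.linalg.cholesky(V + jitter * np.eye(len(V)))
        z = rng.standard_normal(len(self.coef_hat))
        return self.coef_hat + L @ z


@dataclass
class ImputedSet:
    """M completed datasets produced by one MI strategy.

    ``applicable`` is False when the strategy's imputation model could not be
    fit (e.g. a cluster with all outcomes missing under within-cluster MI);
    ``datasets`` is then empty and ``failures`` records the reasons.
    """

    M: int
    datasets: list[pd.DataFrame]
    strategy: str
    applicable: bool = True
    failures: dict = field(default_factory=dict)


def complete_case(data: pd.DataFrame) -> pd.DataFrame:
    """Drop rows with missing outcome, leaving everything else untouched."""
    out = data.dropna(subset=["outcome"])
    if len(out) == 0:
        raise ValueError("all outcomes are missing; nothing left to analyze")
    return out.copy()


def _fit_logistic(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Plain ML logistic fit returning (coef, covariance).

    Raises :class:`ImputationError` on separation or non-convergence.
    """
    if y.min() == y.max():
        raise ImputationError("observed outcomes are all identical")
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        coef = np.asarray(res.params, float)
        cov = np.asarray(res.cov_params(), float)
    except Exception as exc:  # pragma: no cover - statsmodels failure modes
        raise ImputationError(f"imputation model failed: {exc}") from exc
    if not (np.all(np.isfinite(coef)) and np.all(np.isfinite(cov))):
        raise ImputationError("non-finite imputation model estimates")
    if np.abs(coef).max() > _SEPARATION_BOUND:
        raise ImputationError("perfect or quasi-perfect separation")
    return coef, cov


def _design(data: pd.DataFrame, covariates: tuple[str, ...]) -> np.ndarray:
    cols = [np.ones(len(data))]
    cols += [data[c].to_numpy(float) for c in covariates]
    return np.column_stack(cols)


class PosteriorDrawImputer(BaseEstimator):
    """Standard MI: posterior-draw logistic imputation ignoring clustering.

    Parameters
    ----------
    covariates : tuple of str
        Columns of the imputation model (default treatment arm + auxiliary
        covariate); an intercept is always included.
    M : int
        Number of completed datasets (default 5).
    """

    def __init__(self, covariates: tuple[str, ...] = ("arm", "covariate"), M: int = 5):
        self.covariates = covariates
        self.M = M

    def fit(self, data: pd.DataFrame):
        """Fit the logistic imputation model on the observed rows."""
        obs = data[data["outcome"].notna()]
        X = _design(obs, tuple(self.covariates))
        coef, cov = _fit_logistic(obs["outcome"].to_numpy(float), X)
        self.model_ = ImputationModel(coef, cov, ("const", *self.covariates))
        return self

    def impute(self, data: pd.DataFrame, rng: np.random.Generator) -> ImputedSet:
        """Fit on the observed rows, then produce M completed copies."""
        try:
            self.fit(data)
        except ImputationError as exc:
            return ImputedSet(self.M, [], "standard", False, {"dataset": str(exc)})
        miss_mask = data["outcome"].isna().to_numpy()
        X_mis = _design(data[miss_mask], tuple(self.covariates))
        datasets = []
        for _ in range(self.M):
            beta = self.model_.draw_coefficients(rng)
            p = special.expit(X_mis @ beta)
            filled = data.copy()
            filled.loc[miss_mask, "outcome"] = (
                rng.random(len(p)) < p
            ).astype(float)
            datasets.append(filled)
        return ImputedSet(self.M, datasets, "standard", True)


class WithinClusterImputer(BaseEstimator):
    """Within-cluster MI: the posterior-draw imputer run per cluster.

    The treatment indicator is constant inside a cluster and is dropped; the
    per-cluster model is intercept + auxiliary covariate (intercept only when
    the observed covariate does not vary).  Any cluster with missing outcomes
    whose observed outcomes are absent or all identical makes the strategy
    inapplicable for the whole dataset.
    """

    def __init__(self, covariate: str = "covariate", M: int = 5):
        self.covariate = covariate
        self.M = M

    def fit(self, data: pd.DataFrame):
        """Fit one logistic model per cluster that contains missing outcomes."""
        models: dict = {}
        failures: dict = {}
        for cid, cl in data.groupby("cluster_id"):
            if not cl["outcome"].isna().any():
                continue
            obs = cl[cl["outcome"].notna()]
            if len(obs) == 0:
                failures[cid] = "all outcomes missing"
                continue
            yobs = obs["outcome"].to_numpy(float)
            if yobs.min() == yobs.max():
                failures[cid] = "all observed outcomes identical"
                continue
            covs = (
                (self.covariate,)
                if obs[self.covariate].nunique() > 1
                else ()
            )
            try:
                coef, cov = _fit_logistic(yobs, _design(obs, covs))
            except ImputationError as exc:
                failures[cid] = str(exc)
                continue
            models[cid] = ImputationModel(coef, cov, ("const", *covs))
        self.models_ = models
        self.failures_ = failures
        return self

    def impute(self, data: pd.DataFrame, rng: np.random.Generator) -> ImputedSet:
        self.fit(data)
        if self.failures_:
            return ImputedSet(self.M, [], "within_cluster", False, dict(self.failures_))
        datasets = [data.copy() for _ in range(self.M)]
        for cid, model in self.models_.items():
            in_cluster = data["cluster_id"].to_numpy() == cid
            miss_mask = in_cluster & data["outcome"].isna().to_numpy()
            X_mis = _design(data[miss_mask], model.covariate_names[1:])
            for filled in datasets:
                beta = model.draw_coefficients(rng)
                p = special.expit(X_mis @ beta)
                filled.loc[miss_mask, "outcome"] = (
                    rng.random(len(p)) < p
                ).astype(float)
        return ImputedSet(self.M, datasets, "within_cluster", True)


def posterior_draw_imputer(
    observed: pd.DataFrame,
    covariates: tuple[str, ...] = ("arm", "covariate"),
    M: int = 5,
    rng: np.random.Generator | None = None,
) -> ImputedSet:
    """Functional form of :class:`PosteriorDrawImputer`."""
    rng = np.random.default_rng() if rng is None else rng
    return PosteriorDrawImputer(covariates=covariates, M=M).impute(observed, rng)


def within_cluster_mi(
    data: pd.DataFrame, M: int = 5, rng: np.random.Generator | None = None
) -> ImputedSet:
    """Functional form of :class:`WithinClusterImputer`."""
    rng = np.random.default_rng() if rng is None else rng
    return WithinClusterImputer(M=M).impute(data, rng)


def write_imputed_set(imp: ImputedSet, outdir) -> None:
    """Serialize an ImputedSet as M CSV files plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = []
    for i, ds in enumerate(imp.datasets, start=1):
        name = f"imputation_{i:02d}.csv"
        ds.to_csv(outdir / name, index=False)
        names.append(name)
    manifest = {
        "strategy": imp.strategy,
        "M": imp.M,
        "applicable": imp.applicable,
        "failures": {str(k): v for k, v in imp.failures.items()},
        "datasets": names,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
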