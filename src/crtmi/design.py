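"""Structural descriptions of a balanced two-arm cluster randomized trial.

A :class:`TrialDesign` captures everything the synthetic-data generator needs
to emulate one simulation scenario: the number of clusters per arm, the common
cluster size, the intracluster correlation coefficient (ICC) of the binary
outcome, and the marginal outcome prevalence in each arm.

A :class:`MissingnessSpec` describes covariate-dependent missingness (CDM):
the overall expected fraction of missing outcomes and the probability ratio by
which subjects with auxiliary covariate 1 are more likely to be missing than
subjects with covariate 0.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TrialDesign", "MissingnessSpec"]


@dataclass(frozen=True)
class TrialDesign:
    """Parameters of one balanced, completely randomized two-arm CRT.

    Parameters
    ----------
    clusters_per_arm : int
        Number of clusters randomized to each arm (J in the small-sample
        correction; k in the complete-data degrees of freedom 2(k-1)).
    cluster_size : int
        Number of subjects in every cluster (balanced design).
    icc : float
        Intracluster correlation coefficient rho of the binary outcome,
        in [0, 1).
    prevalence_control, prevalence_intervention : float
        Marginal outcome prevalences pi_c and pi_t, each in (0, 1).
    """

    clusters_per_arm: int
    cluster_size: int
    icc: float
    prevalence_control: float = 0.40
    prevalence_intervention: float = 0.30

    def __post_init__(self) -> None:
        if self.clusters_per_arm < 1:
            raise ValueError("clusters_per_arm must be a positive integer")
        if self.cluster_size < 1:
            raise ValueError("cluster_size must be a positive integer")
        if not 0.0 <= self.icc < 1.0:
            raise ValueError(f"icc must lie in [0, 1), got {self.icc}")
        for name in ("prevalence_control", "prevalence_intervention"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {p}")

    @property
    def vif(self) -> float:
        """Design effect 1 + (m - 1) * rho (variance inflation factor)."""
        return 1.0 + (self.cluster_size - 1) * self.icc

    @property
    def n_total(self) -> int:
        """Total number of subjects, 2 * clusters_per_arm * cluster_size."""
        return 2 * self.clusters_per_arm * self.cluster_size


@dataclass(frozen=True)
class MissingnessSpec:
    """Covariate-dependent missingness with a probability-ratio structure.

    A subject's outcome is missing with probability ``p0`` when the auxiliary
    binary covariate is 0 and ``p1 = risk_ratio * p0`` when it is 1.  Because
    the covariate is Bernoulli(0.5), the overall expected missing fraction is
    ``(p0 + p1) / 2 = target_rate``, which pins down ``p0``.
    """

    target_rate: float
    risk_ratio: float = 1.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_rate < 1.0:
            raise ValueError("target_rate must lie in [0, 1)")
        if self.risk_ratio <= 0:
            raise ValueError("risk_ratio must be positive")
        if self.p1 > 1.0:
            raise ValueError(
                f"infeasible spec: p1 = {self.p1:.4f} exceeds 1 "
                f"(target_rate {self.target_rate}, risk_ratio {self.risk_ratio})"
            )

    @property
    def p0(self) -> float:
        """Missingness probability for covariate == 0 subjects."""
        return 2.0 * self.target_rate / (1.0 + self.risk_ratio)

    @property
    def p1(self) -> float:
        """Missingness probability for covariate == 1 subjects."""
        return self.risk_ratio * self.p0
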