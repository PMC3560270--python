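"""Orchestration of the full factorial Monte-Carlo experiment.

One *cell* of the experiment is a (design, ICC, missing%, strategy,
analyzer) combination; a *replicate* is one simulated trial.  Within a
replicate the generated dataset and its missingness pattern are shared by
every strategy and analyzer (a single data stream), so cross-method
contrasts are paired and replicate seeds depend only on the design cell and
replicate index, never on the strategy or analyzer.

At 0% missing every strategy collapses to direct analysis of the complete
data.  Replicates where a model does not converge, or where within-cluster
MI is inapplicable, are excluded from that cell's metrics and counted; a
cell whose strategy fails in more than half of the replicates is reported as
NA (NaN metrics with the failure count retained).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import MissingnessSpec, TrialDesign
from .gee import fit_gee, wald_interval
from .generate import generate_trial, impose_cdm
from .impute import PosteriorDrawImputer, WithinClusterImputer, complete_case
from .metrics import ScenarioMetrics, compute_metrics, true_effect
from .pooling import rubin_pool
from .relr import fit_relr

__all__ = [
    "ScenarioGrid",
    "default_designs",
    "run_replicates",
    "run_cell",
    "run_grid",
    "summarize_records",
    "format_table",
    "STRATEGIES",
    "ANALYZERS",
]

STRATEGIES = ("complete_case", "standard_mi", "within_cluster_mi")
ANALYZERS = ("gee", "relr")


def default_designs() -> list[TrialDesign]:
    """The nine study designs: S-design 5x500 and L-designs 20x50, 30x30."""
    cells = [
        (5, 500, (0.001, 0.01, 0.05)),
        (20, 50, (0.01, 0.05, 0.1)),
        (30, 30, (0.05, 0.1, 0.2)),
    ]
    return [
        TrialDesign(clusters_per_arm=k, cluster_size=m, icc=rho)
        for k, m, iccs in cells
        for rho in iccs
    ]


@dataclass
class ScenarioGrid:
    """Full experiment specification (defaults mirror the study grid)."""

    designs: list[TrialDesign] = field(default_factory=default_designs)
    missing_rates: tuple[float, ...] = (0.0, 0.15, 0.30)
    strategies: tuple[str, ...] = STRATEGIES
    analyzers: tuple[str, ...] = ANALYZERS
    replications: int = 1000
    M: int = 5
    master_seed: int = 20130109
    risk_ratio: float = 1.3
    relr_truth: str = "conditional"


def _cell_key(design: TrialDesign, missing_rate: float) -> tuple[int, ...]:
    return (
        design.clusters_per_arm,
        design.cluster_size,
        int(round(design.icc * 1_000_000)),
        int(round(missing_rate * 1000)),
    )


def _replicate_rngs(master_seed, design, missing_rate, rep):
    """Data stream shared by all strategies; separate streams per MI strategy."""
    key = _cell_key(design, missing_rate)
    data_rng = np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(*key, rep, 0))
    )
    mi_rngs = {
        "standard_mi": np.random.default_rng(
            np.random.SeedSequence(master_seed, spawn_key=(*key, rep, 1))
        ),
        "within_cluster_mi": np.random.default_rng(
            np.random.SeedSequence(master_seed, spawn_key=(*key, rep, 2))
        ),
    }
    return data_rng, mi_rngs


def _fit_one(analyzer: str, df: pd.DataFrame, design: TrialDesign):
    """Fit one analyzer; returns (estimate, se, ok, extras)."""
    if analyzer == "gee":
        fit = fit_gee(df, clusters_per_arm=design.clusters_per_arm)
        return (
            float(fit.params_[1]),
            float(fit.robust_se_[1]),
            fit.converged_,
            {"working_alpha": fit.working_alpha_},
        )
    if analyzer == "relr":
        fit = fit_relr(df)
        ok = fit.converged_ and not fit.boundary_
        return (
            float(fit.params_[1]),
            float(fit.se_[1]) if ok else float("nan"),
            ok,
            {"sigma_b2": fit.sigma_b2_, "boundary": fit.boundary_},
        )
    raise ValueError(f"unknown analyzer {analyzer!r}")


def run_replicates(
    design: TrialDesign,
    missing_rate: float,
    strategies=STRATEGIES,
    analyzers=ANALYZERS,
    replications: int = 1000,
    M: int = 5,
    master_seed: int = 20130109,
    risk_ratio: float = 1.3,
    level: float = 0.95,
) -> pd.DataFrame:
    """Replicate-level fit records for every requested strategy x analyzer.

    Returns a long DataFrame with columns replicate, strategy, analyzer,
    estimate, se, ci_lo, ci_hi, ok, note.
    """
    spec = (
        MissingnessSpec(missing_rate, risk_ratio) if missing_rate > 0 else None
    )
    rows: list[dict] = []

    def record(rep, strategy, analyzer, est, se, lo, hi, ok, note="", extras=None):
        rows.append(
            {
                "replicate": rep,
                "strategy": strategy,
                "analyzer": analyzer,
                "estimate": est,
                "se": se,
                "ci_lo": lo,
                "ci_hi": hi,
                "ok": ok,
                "note": note,
                "sigma_b2": (extras or {}).get("sigma_b2", np.nan),
                "working_alpha": (extras or {}).get("working_alpha", np.nan),
            }
        )

    for rep in range(replications):
        data_rng, mi_rngs = _replicate_rngs(master_seed, design, missing_rate, rep)
        complete = generate_trial(design, data_rng)
        incomplete = (
            impose_cdm(complete, spec, data_rng) if spec is not None else complete
        )

        if spec is None:
            # 0% missing: strategies are indistinguishable from direct analysis
            for analyzer in analyzers:
                try:
                    est, se, ok, extras = _fit_one(analyzer, complete, design)
                except ValueError:
                    est = se = float("nan")
                    ok = False
                    extras = None
                lo, hi = wald_interval(est, se, level) if ok else (np.nan, np.nan)
                for strategy in strategies:
                    record(rep, strategy, analyzer, est, se, lo, hi, ok, extras=extras)
            continue

        for strategy in strategies:
            if strategy == "complete_case":
                cc = complete_case(incomplete)
                for analyzer in analyzers:
                    try:
                        est, se, ok, extras = _fit_one(analyzer, cc, design)
                    except ValueError:
                        est = se = float("nan")
                        ok = False
                        extras = None
                    lo, hi = (
                        wald_interval(est, se, level) if ok else (np.nan, np.nan)
                    )
                    record(rep, strategy, analyzer, est, se, lo, hi, ok, extras=extras)
                continue

            imputer = (
                PosteriorDrawImputer(M=M)
                if strategy == "standard_mi"
                else WithinClusterImputer(M=M)
            )
            imp = imputer.impute(incomplete, mi_rngs[strategy])
            if not imp.applicable:
                for analyzer in analyzers:
                    record(
                        rep, strategy, analyzer,
                        np.nan, np.nan, np.nan, np.nan, False, "inapplicable",
                    )
                continue
            for analyzer in analyzers:
                ests, ses = [], []
                all_ok = True
                for ds in imp.datasets:
                    try:
                        est_m, se_m, ok_m, _ = _fit_one(analyzer, ds, design)
                    except ValueError:
                        ok_m = False
                    if not ok_m:
                        all_ok = False
                        break
                    ests.append(est_m)
                    ses.append(se_m)
                if not all_ok:
                    record(
                        rep, strategy, analyzer,
                        np.nan, np.nan, np.nan, np.nan, False, "fit failure",
                    )
                    continue
                pooled = rubin_pool(
                    ests,
                    np.square(ses),
                    clusters_per_arm=design.clusters_per_arm,
                    level=level,
                )
                record(
                    rep, strategy, analyzer,
                    pooled.beta_bar, np.sqrt(pooled.total_var),
                    pooled.ci[0], pooled.ci[1], True,
                )

    return pd.DataFrame(rows)


def summarize_records(
    records: pd.DataFrame,
    design: TrialDesign,
    strategy: str,
    analyzer: str,
    relr_truth: str = "conditional",
) -> ScenarioMetrics:
    """Reduce one cell's replicate records to ScenarioMetrics.

    Cells where more than half the replicates failed (convergence or MI
    applicability) are reported as NA: NaN metrics with counts retained.
    """
    sub = records[
        (records["strategy"] == strategy) & (records["analyzer"] == analyzer)
    ]
    n_failed = int((~sub["ok"]).sum())
    good = sub[sub["ok"]]
    if len(good) < max(2, len(sub) / 2):
        return ScenarioMetrics(
            float("nan"), float("nan"), float("nan"), float("nan"),
            float("nan"), len(good), n_failed,
        )
    truth = true_effect(
        "marginal" if analyzer == "gee" else relr_truth, design
    )
    return compute_metrics(
        good["estimate"].to_numpy(),
        good["se"].to_numpy(),
        good[["ci_lo", "ci_hi"]].to_numpy(),
        truth,
        n_failed=n_failed,
    )


def run_cell(
    design: TrialDesign,
    missing_rate: float,
    strategy: str,
    analyzer: str,
    replications: int = 1000,
    M: int = 5,
    master_seed: int = 20130109,
    risk_ratio: float = 1.3,
    relr_truth: str = "conditional",
    level: float = 0.95,
) -> ScenarioMetrics:
    """Run one grid cell end to end and return its metrics."""
    records = run_replicates(
        design,
        missing_rate,
        strategies=(strategy,),
        analyzers=(analyzer,),
        replications=replications,
        M=M,
        master_seed=master_seed,
        risk_ratio=risk_ratio,
        level=level,
    )
    return summarize_records(records, design, strategy, analyzer, relr_truth)


def run_grid(grid: ScenarioGrid, level: float = 0.95) -> pd.DataFrame:
    """Run every cell of the grid; one row per cell with all metrics.

    Monte-Carlo standard errors accompany the point metrics so reduced
    replication counts can be interpreted: ``mc_se_coverage`` is the binomial
    SE of the coverage estimate and ``mc_se_estimate`` the SE of the mean
    treatment estimate.
    """
    out = []
    for design in grid.designs:
        for rate in grid.missing_rates:
            records = run_replicates(
                design,
                rate,
                strategies=grid.strategies,
                analyzers=grid.analyzers,
                replications=grid.replications,
                M=grid.M,
                master_seed=grid.master_seed,
                risk_ratio=grid.risk_ratio,
                level=level,
            )
            for strategy in grid.strategies:
                for analyzer in grid.analyzers:
                    m = summarize_records(
                        records, design, strategy, analyzer, grid.relr_truth
                    )
                    cov_se = (
                        np.sqrt(m.coverage * (1 - m.coverage) / m.n_used)
                        if m.n_used and np.isfinite(m.coverage)
                        else float("nan")
                    )
                    est_se = (
                        m.sd_of_estimates / np.sqrt(m.n_used)
                        if m.n_used and np.isfinite(m.sd_of_estimates)
                        else float("nan")
                    )
                    out.append(
                        {
                            "clusters_per_arm": design.clusters_per_arm,
                            "cluster_size": design.cluster_size,
                            "icc": design.icc,
                            "vif": design.vif,
                            "missing_rate": rate,
                            "strategy": strategy,
                            "analyzer": analyzer,
                            "standardized_bias": m.standardized_bias,
                            "mean_model_se": m.mean_model_se,
                            "rmse": m.rmse,
                            "coverage": m.coverage,
                            "sd_of_estimates": m.sd_of_estimates,
                            "n_used": m.n_used,
                            "n_failed": m.n_failed,
                            "mc_se_coverage": cov_se,
                            "mc_se_estimate": est_se,
                        }
                    )
    return pd.DataFrame(out)


def format_table(cells: pd.DataFrame, metric: str) -> str:
    """Render one metric as a text table mirroring the study's layout.

    Rows are (design, ICC, missing%); columns are strategy x analyzer, with
    NA for cells that failed in most replicates.
    """
    sub = cells.copy()
    pivot = sub.pivot_table(
        index=["clusters_per_arm", "cluster_size", "icc", "missing_rate"],
        columns=["strategy", "analyzer"],
        values=metric,
        sort=False,
    )
    # at 0% missing all strategies coincide; keep complete_case only
    order = [
        (s, a)
        for s in STRATEGIES
        for a in ANALYZERS
        if (s, a) in pivot.columns
    ]
    pivot = pivot[order]
    with pd.option_context("display.float_format", lambda v: f"{v:.2f}"):
        text = pivot.to_string(na_rep="NA")
    return f"{metric}\n{text}\n"
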