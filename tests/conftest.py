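"""Shared fixtures: small deterministic datasets and session-scoped
Monte-Carlo cells reused by several acceptance checks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from crtmi import TrialDesign, generate_trial, run_replicates

SEED = 20130109


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_trial(rng):
    """One 4-clusters-per-arm, 50-subject trial with moderate clustering."""
    return generate_trial(TrialDesign(4, 50, 0.05), rng)


@pytest.fixture()
def tiny_fixture():
    """Hand-sized clustered dataset (4 clusters x 3 subjects) for oracles."""
    rng = np.random.default_rng(7)
    clusters = np.repeat([0, 1, 2, 3], 3)
    arm = np.repeat([0, 0, 1, 1], 3)
    y = np.array([0, 1, 1, 0, 0, 1, 1, 1, 0, 0, 1, 0], float)
    cov = rng.integers(0, 2, 12)
    return pd.DataFrame(
        {"cluster_id": clusters, "arm": arm, "covariate": cov, "outcome": y}
    )


# ---------------------------------------------------------------------------
# Session-scoped Monte-Carlo cells.  Replication counts are chosen so each
# check's Monte-Carlo error is small against its tolerance while the whole
# suite stays desk-scale; the headline complete-data cell runs at the study's
# full 1000 replications because standardized bias has MC error ~1/sqrt(n).
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def cell_s_low_complete():
    """S-design (5x500) at ICC 0.001, complete data, both analyzers, 1000 reps."""
    design = TrialDesign(5, 500, 0.001)
    rec = run_replicates(
        design, 0.0, strategies=("complete_case",),
        analyzers=("gee", "relr"), replications=1000, master_seed=SEED,
    )
    return design, rec


@pytest.fixture(scope="session")
def cell_s_high_complete():
    """S-design at ICC 0.05, complete data, both analyzers, 300 reps."""
    design = TrialDesign(5, 500, 0.05)
    rec = run_replicates(
        design, 0.0, strategies=("complete_case",),
        analyzers=("gee", "relr"), replications=300, master_seed=SEED,
    )
    return design, rec


@pytest.fixture(scope="session")
def cell_s_mid_smi30():
    """S-design at ICC 0.01, 30% missing, standard MI + GEE, 200 reps."""
    design = TrialDesign(5, 500, 0.01)
    rec = run_replicates(
        design, 0.30, strategies=("standard_mi",),
        analyzers=("gee",), replications=200, master_seed=SEED,
    )
    return design, rec


@pytest.fixture(scope="session")
def cell_s_high_cc15():
    """S-design at ICC 0.05, 15% missing, complete case + GEE, 400 reps."""
    design = TrialDesign(5, 500, 0.05)
    rec = run_replicates(
        design, 0.15, strategies=("complete_case",),
        analyzers=("gee",), replications=400, master_seed=SEED,
    )
    return design, rec


@pytest.fixture(scope="session")
def cell_l30_complete():
    """30/arm x 30 design at ICC 0.05, complete data, GEE, 600 reps."""
    design = TrialDesign(30, 30, 0.05)
    rec = run_replicates(
        design, 0.0, strategies=("complete_case",),
        analyzers=("gee",), replications=600, master_seed=SEED,
    )
    return design, rec


@pytest.fixture(scope="session")
def cell_s_high_cc30_relr():
    """S-design at ICC 0.05, 30% missing, complete case + RELR, 400 reps."""
    design = TrialDesign(5, 500, 0.05)
    rec = run_replicates(
        design, 0.30, strategies=("complete_case",),
        analyzers=("relr",), replications=400, master_seed=SEED,
    )
    return design, rec


@pytest.fixture(scope="session")
def cell_s_low_wcmi15():
    """S-design at ICC 0.001, 15% missing, within-cluster MI + GEE, 300 reps."""
    design = TrialDesign(5, 500, 0.001)
    rec = run_replicates(
        design, 0.15, strategies=("within_cluster_mi",),
        analyzers=("gee",), replications=300, master_seed=SEED,
    )
    return design, rec


@pytest.fixture(scope="session")
def cell_s_high_smi30():
    """S-design at ICC 0.05 (VIF ~26), 30% missing, standard MI + GEE, 150 reps."""
    design = TrialDesign(5, 500, 0.05)
    rec = run_replicates(
        design, 0.30, strategies=("standard_mi",),
        analyzers=("gee",), replications=150, master_seed=SEED,
    )
    return design, rec


@pytest.fixture(scope="session")
def cell_l_design_recovery():
    """20/arm x 50 design at ICC 0.1, complete data, both analyzers, 250 reps.

    Used for the variance-component recovery and marginal/conditional
    attenuation checks.
    """
    design = TrialDesign(20, 50, 0.1)
    rec = run_replicates(
        design, 0.0, strategies=("complete_case",),
        analyzers=("gee", "relr"), replications=250, master_seed=SEED,
    )
    return design, rec
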