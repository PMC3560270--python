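import math

import numpy as np
import pandas as pd
import pytest

from crtmi import (
    MissingnessSpec,
    TrialDesign,
    anova_icc,
    beta_params,
    generate_trial,
    impose_cdm,
    read_trial_csv,
    write_trial_csv,
)

MARGINAL_LOR = math.log((0.3 / 0.7) / (0.4 / 0.6))  # -0.44183


class TestBetaParams:
    @pytest.mark.parametrize(
        "prev,icc,alpha,beta",
        [(0.40, 0.05, 7.6, 11.4), (0.30, 0.5, 0.3, 0.7)],
    )
    def test_moment_matching_examples(self, prev, icc, alpha, beta):
        a, b = beta_params(prev, icc)
        assert a == pytest.approx(alpha)
        assert b == pytest.approx(beta)
        # mean = prevalence and pairwise correlation 1/(a+b+1) = icc
        assert a / (a + b) == pytest.approx(prev)
        assert 1 / (a + b + 1) == pytest.approx(icc)

    def test_no_clustering_limit(self):
        a, b = beta_params(0.5, 1e-8)
        assert a == b
        assert a > 1e7  # alpha = beta -> infinity, mean pinned at 0.5

    def test_degenerate_icc_rejected(self):
        with pytest.raises(ValueError):
            beta_params(0.4, 0.0)
        with pytest.raises(ValueError):
            beta_params(1.2, 0.1)


class TestGenerateTrial:
    def test_structure_balanced(self, rng):
        d = TrialDesign(4, 25, 0.1)
        df = generate_trial(d, rng)
        assert len(df) == d.n_total
        per_cluster = df.groupby("cluster_id").agg(
            n=("outcome", "size"), arms=("arm", "nunique")
        )
        assert (per_cluster["n"] == 25).all()
        assert (per_cluster["arms"] == 1).all()  # each cluster in one arm
        assert df.groupby("arm")["cluster_id"].nunique().tolist() == [4, 4]
        assert not df["outcome"].isna().any()

    def test_moments_recover_design(self):
        """Arm prevalences and ANOVA ICC match the generator over replicates."""
        d = TrialDesign(10, 20, 0.1)
        prev_c, prev_t, iccs = [], [], []
        for i in range(2000):
            df = generate_trial(d, np.random.default_rng((900, i)))
            means = df.groupby("arm")["outcome"].mean()
            prev_c.append(means[0])
            prev_t.append(means[1])
            iccs.append(anova_icc(df))
        for vals, target in [(prev_c, 0.40), (prev_t, 0.30)]:
            vals = np.asarray(vals)
            sem = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - target) < 3 * sem
        iccs = np.asarray(iccs)
        sem = iccs.std(ddof=1) / np.sqrt(len(iccs))
        # the mean-squares ICC estimator itself carries a small O(1/K)
        # downward bias (~5% of rho at 20 clusters); allow for it on top of
        # the Monte-Carlo band
        assert abs(iccs.mean() - 0.1) < 3 * sem + 0.05 * 0.1

    def test_icc_zero_gives_independent_bernoulli(self):
        """Cluster totals have binomial variance m*pi*(1-pi) when icc=0."""
        d = TrialDesign(500, 20, 0.0)
        df = generate_trial(d, np.random.default_rng(11))
        control = df[df["arm"] == 0]
        totals = control.groupby("cluster_id")["outcome"].sum().to_numpy()
        expected_var = 20 * 0.4 * 0.6
        # chi-square MC band for the variance of 500 cluster totals
        assert abs(totals.var(ddof=1) - expected_var) < 4 * expected_var * np.sqrt(
            2 / 499
        )

    def test_marginal_log_odds_ratio_recovered(self, cell_s_low_complete):
        """Mean GEE estimate approaches log((0.3/0.7)/(0.4/0.6)) = -0.4418."""
        _, rec = cell_s_low_complete
        est = rec[(rec.analyzer == "gee") & rec.ok]["estimate"].to_numpy()
        sem = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - MARGINAL_LOR) < 3 * sem

    def test_seeded_determinism(self):
        d = TrialDesign(5, 40, 0.05)
        a = generate_trial(d, np.random.default_rng(77))
        b = generate_trial(d, np.random.default_rng(77))
        pd.testing.assert_frame_equal(a, b)


class TestImposeCdm:
    def test_zero_rate_identity(self, small_trial, rng):
        out = impose_cdm(small_trial, MissingnessSpec(0.0), rng)
        pd.testing.assert_frame_equal(out, small_trial)

    def test_stratum_rates_and_overall_fraction(self):
        d = TrialDesign(10, 2000, 0.0)
        rng = np.random.default_rng(5)
        df = generate_trial(d, rng)
        spec = MissingnessSpec(0.30, 1.3)
        out = impose_cdm(df, spec, rng)
        miss = out["outcome"].isna()
        for cov_value, p in [(0, spec.p0), (1, spec.p1)]:
            sub = miss[out["covariate"] == cov_value]
            sem = np.sqrt(p * (1 - p) / len(sub))
            assert abs(sub.mean() - p) < 4 * sem
        assert abs(miss.mean() - 0.30) < 0.01
        # arm and covariates never missing
        assert not out[["cluster_id", "arm", "covariate"]].isna().any().any()

    def test_missingness_ignores_outcome(self):
        """Within a covariate stratum, missingness is unrelated to the outcome."""
        d = TrialDesign(10, 4000, 0.0)
        rng = np.random.default_rng(8)
        df = generate_trial(d, rng)
        out = impose_cdm(df, MissingnessSpec(0.30, 1.3), rng)
        merged = df.assign(miss=out["outcome"].isna())
        for cov_value in (0, 1):
            sub = merged[merged["covariate"] == cov_value]
            rates = sub.groupby("outcome")["miss"].mean()
            n = sub.groupby("outcome")["miss"].size().min()
            assert abs(rates[0.0] - rates[1.0]) < 4 * np.sqrt(0.3 * 0.7 * 2 / n)

    def test_incomplete_input_rejected(self, small_trial, rng):
        once = impose_cdm(small_trial, MissingnessSpec(0.15), rng)
        with pytest.raises(ValueError, match="complete"):
            impose_cdm(once, MissingnessSpec(0.15), rng)


def test_csv_roundtrip(tmp_path, small_trial, rng):
    data = impose_cdm(small_trial, MissingnessSpec(0.15), rng)
    path = tmp_path / "trial.csv"
    write_trial_csv(data, path)
    # missing outcomes serialize as empty fields
    assert ",\n" in path.read_text() or path.read_text().endswith(",")
    back = read_trial_csv(path)
    pd.testing.assert_frame_equal(
        back, data.reset_index(drop=True), check_dtype=False
    )
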