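import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from crtmi import (
    ImputationModel,
    MissingnessSpec,
    PosteriorDrawImputer,
    TrialDesign,
    WithinClusterImputer,
    complete_case,
    fit_gee,
    generate_trial,
    impose_cdm,
    rubin_pool,
    write_imputed_set,
)


@pytest.fixture()
def incomplete_trial(rng):
    d = TrialDesign(4, 100, 0.02)
    data = generate_trial(d, rng)
    return impose_cdm(data, MissingnessSpec(0.20), rng)


class TestCompleteCase:
    def test_drops_only_missing_rows(self, incomplete_trial):
        out = complete_case(incomplete_trial)
        kept = incomplete_trial.dropna(subset=["outcome"])
        pd.testing.assert_frame_equal(out, kept)

    def test_identity_without_missingness(self, small_trial):
        pd.testing.assert_frame_equal(complete_case(small_trial), small_trial)

    def test_all_missing_rejected(self, small_trial):
        allmiss = small_trial.assign(outcome=np.nan)
        with pytest.raises(ValueError):
            complete_case(allmiss)


class TestPosteriorDraw:
    def test_draws_reproduce_model_moments(self):
        """beta_tilde = beta_hat + L Z has mean beta_hat and covariance V."""
        beta = np.array([0.0, 0.5, -0.3])
        V = 0.01 * np.eye(3)
        model = ImputationModel(beta, V, ("const", "arm", "covariate"))
        rng = np.random.default_rng(10)
        draws = np.array([model.draw_coefficients(rng) for _ in range(10_000)])
        se_mean = 0.1 / np.sqrt(10_000)
        np.testing.assert_allclose(draws.mean(0), beta, atol=3.5 * se_mean)
        cov = np.cov(draws.T)
        np.testing.assert_allclose(cov, V, atol=3.5 * 0.01 * np.sqrt(2 / 10_000))

    def test_zero_covariance_gives_point_mass_bernoulli(self, rng):
        """With V=0 imputations are i.i.d. Bernoulli(expit(x' beta_hat))."""
        beta = np.array([0.3, -0.2, 0.1])
        model = ImputationModel(beta, np.zeros((3, 3)), ("c", "arm", "covariate"))
        assert np.array_equal(model.draw_coefficients(rng), beta)
        x = np.array([1.0, 1.0, 0.0])
        p = expit(x @ beta)
        u = rng.random(20_000)
        freq = (u < p).mean()
        assert freq == pytest.approx(p, abs=3.5 * np.sqrt(p * (1 - p) / 20_000))

    def test_observed_cells_untouched_and_imputed_binary(self, incomplete_trial, rng):
        imp = PosteriorDrawImputer(M=5).impute(incomplete_trial, rng)
        assert imp.applicable and len(imp.datasets) == 5
        obs_mask = incomplete_trial["outcome"].notna()
        for ds in imp.datasets:
            assert not ds["outcome"].isna().any()
            pd.testing.assert_series_equal(
                ds.loc[obs_mask, "outcome"],
                incomplete_trial.loc[obs_mask, "outcome"],
            )
            assert ds.loc[~obs_mask, "outcome"].isin([0.0, 1.0]).all()

    def test_reproducible_with_seed(self, incomplete_trial):
        a = PosteriorDrawImputer(M=1).impute(
            incomplete_trial, np.random.default_rng(42)
        )
        b = PosteriorDrawImputer(M=1).impute(
            incomplete_trial, np.random.default_rng(42)
        )
        pd.testing.assert_frame_equal(a.datasets[0], b.datasets[0])

    def test_ignores_cluster_membership(self, incomplete_trial):
        """Standard MI treats subjects as independent: permuting cluster ids
        leaves the imputation (same seed) unchanged."""
        relabeled = incomplete_trial.copy()
        relabeled["cluster_id"] = (relabeled["cluster_id"] * 13 + 5) % 29
        a = PosteriorDrawImputer(M=2).impute(
            incomplete_trial, np.random.default_rng(6)
        )
        b = PosteriorDrawImputer(M=2).impute(relabeled, np.random.default_rng(6))
        for da, db in zip(a.datasets, b.datasets):
            np.testing.assert_array_equal(da["outcome"], db["outcome"])

    def test_single_missing_value_pooled_near_complete_fit(self, rng):
        """As the missing fraction vanishes, pooled MI matches the
        complete-data analysis."""
        d = TrialDesign(5, 200, 0.02)
        data = generate_trial(d, rng)
        full_fit = fit_gee(data)
        holed = data.copy()
        holed.loc[3, "outcome"] = np.nan
        imp = PosteriorDrawImputer(M=5).impute(holed, rng)
        ests, ses = [], []
        for ds in imp.datasets:
            f = fit_gee(ds)
            ests.append(f.params_[1])
            ses.append(f.robust_se_[1])
        pooled = rubin_pool(ests, np.square(ses), clusters_per_arm=5)
        assert pooled.beta_bar == pytest.approx(full_fit.params_[1], abs=0.01)

    def test_degenerate_observed_outcomes_flagged(self, small_trial, rng):
        degenerate = small_trial.copy()
        degenerate["outcome"] = 1.0
        degenerate.loc[:10, "outcome"] = np.nan
        imp = PosteriorDrawImputer().impute(degenerate, rng)
        assert not imp.applicable
        assert imp.datasets == []


class TestWithinCluster:
    def test_locality(self, rng):
        """Imputations in a cluster depend only on that cluster's data."""
        d = TrialDesign(3, 30, 0.05)
        data = generate_trial(d, rng)
        target = data["cluster_id"] == 0
        data.loc[data[target].index[:5], "outcome"] = np.nan

        perturbed = data.copy()
        others = ~target
        # permute outcomes in the other (complete) clusters
        perturbed.loc[others, "outcome"] = (
            perturbed.loc[others, "outcome"].sample(frac=1.0, random_state=3).values
        )

        a = WithinClusterImputer(M=3).impute(data, np.random.default_rng(8))
        b = WithinClusterImputer(M=3).impute(perturbed, np.random.default_rng(8))
        assert a.applicable and b.applicable
        for da, db in zip(a.datasets, b.datasets):
            np.testing.assert_array_equal(
                da.loc[target, "outcome"], db.loc[target, "outcome"]
            )

    def test_treatment_dropped_within_cluster(self, incomplete_trial, rng):
        imputer = WithinClusterImputer(M=2)
        imputer.fit(incomplete_trial)
        for model in imputer.models_.values():
            assert "arm" not in model.covariate_names

    @pytest.mark.parametrize("failure", ["all_missing", "identical_observed"])
    def test_inapplicability_conditions(self, rng, failure):
        d = TrialDesign(3, 20, 0.05)
        data = generate_trial(d, rng)
        cluster0 = data["cluster_id"] == 0
        if failure == "all_missing":
            data.loc[cluster0, "outcome"] = np.nan
        else:
            data.loc[cluster0, "outcome"] = 1.0
            data.loc[data[cluster0].index[:4], "outcome"] = np.nan
        imp = WithinClusterImputer().impute(data, rng)
        assert not imp.applicable
        assert 0 in imp.failures
        assert imp.datasets == []


def test_serialization_roundtrip(tmp_path, incomplete_trial, rng):
    imp = PosteriorDrawImputer(M=3).impute(incomplete_trial, rng)
    write_imputed_set(imp, tmp_path)
    import json

    manifest = json.loads((tmp_path / "manifest.json").read_text())
    assert manifest["strategy"] == "standard"
    assert manifest["applicable"] is True
    assert len(manifest["datasets"]) == 3
    back = pd.read_csv(tmp_path / manifest["datasets"][0])
    assert not back["outcome"].isna().any()
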