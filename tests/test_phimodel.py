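import numpy as np
import pandas as pd
import pytest

from frrfprod.phimodel import (
    BootstrapScheme,
    CANDIDATE_TERMS,
    ElectronRequirementModel,
    collinearity_screen,
    default_schemes,
    fit_gamma_glm,
    rank_all_submodels,
    stratified_bootstrap,
    transform_standardise,
)


def make_phi_records(n_per_date=20, dates=("d1", "d2"), basin="south", seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for date in dates:
        depths = rng.uniform(0.0, 5.5, n_per_date)
        for z in depths:
            rows.append({"date": date, "basin": basin, "depth_m": z,
                         "phi_e_c": rng.gamma(5.0, 1.5)})
    return pd.DataFrame(rows)


class TestStratifiedBootstrap:
    def test_scheme_row_budgets(self):
        assert BootstrapScheme.north().n_per_date == 240
        assert BootstrapScheme.south().n_per_date == 240

    def test_default_campaign_counts(self, default_campaign):
        """14 dates, 7 per basin: 240 rows per date, 1680 per basin, 3360 total."""
        _, _, _, truth = default_campaign
        boot = stratified_bootstrap(truth, default_schemes(), seed=5)
        assert len(boot) == 3360
        assert (boot.groupby("date").size() == 240).all()
        assert boot.groupby("basin").size().to_dict() == {"north": 1680, "south": 1680}

    def test_single_date_gives_240(self):
        records = make_phi_records(n_per_date=30, dates=("only",))
        boot = stratified_bootstrap(records, default_schemes(), seed=1)
        assert len(boot) == 240

    def test_singleton_stratum_resamples_identically(self):
        rows = pd.DataFrame(
            {
                "date": ["d"] * 3,
                "basin": ["south"] * 3,
                "depth_m": [0.5, 2.0, 4.0],  # one record per stratum
                "phi_e_c": [3.0, 5.0, 7.0],
            }
        )
        boot = stratified_bootstrap(rows, default_schemes(), seed=2)
        assert len(boot) == 240
        assert sorted(boot["phi_e_c"].unique()) == [3.0, 5.0, 7.0]
        assert (boot.groupby("phi_e_c").size() == 80).all()

    def test_empty_stratum_raises_with_context(self):
        rows = pd.DataFrame(
            {"date": ["d"], "basin": ["south"], "depth_m": [0.5], "phi_e_c": [3.0]}
        )
        with pytest.raises(ValueError, match=r"\[1\.0, 3\.0\].*d"):
            stratified_bootstrap(rows, default_schemes(), seed=0)

    def test_reproducible_under_seed(self):
        records = make_phi_records()
        a = stratified_bootstrap(records, default_schemes(), seed=9)
        b = stratified_bootstrap(records, default_schemes(), seed=9)
        pd.testing.assert_frame_equal(a, b)
        c = stratified_bootstrap(records, default_schemes(), seed=10)
        assert not a["phi_e_c"].equals(c["phi_e_c"])


class TestCollinearityScreen:
    def test_duplicated_column_flagged(self, rng):
        df = pd.DataFrame({"a": rng.uniform(1, 2, 100)})
        df["b"] = df["a"]
        df["c"] = rng.uniform(1, 2, 100)
        result = collinearity_screen(df, ["a", "b", "c"])
        assert any({p[0], p[1]} == {"a", "b"} for p in result.flagged_pairs)
        assert "b" in result.dropped and "a" in result.retained

    def test_strongly_correlated_pair_flagged(self, rng):
        x = rng.normal(size=2000)
        df = pd.DataFrame({"x": np.exp(x), "y": np.exp(0.96 * x + 0.2 * rng.normal(size=2000))})
        result = collinearity_screen(df, ["x", "y"])
        assert len(result.flagged_pairs) == 1
        assert abs(result.flagged_pairs[0][2]) >= 0.7

    def test_independent_columns_not_flagged(self, rng):
        df = pd.DataFrame(rng.uniform(1, 2, size=(1000, 6)), columns=list("abcdef"))
        result = collinearity_screen(df, list("abcdef"))
        assert result.flagged_pairs == ()
        assert result.retained == tuple("abcdef")

    def test_constant_column_reported(self, rng):
        df = pd.DataFrame({"a": rng.uniform(1, 2, 50), "b": np.ones(50)})
        result = collinearity_screen(df, ["a", "b"])
        assert result.constant_columns == ("b",)
        assert "b" in result.dropped


class TestTransformStandardise:
    def test_output_is_standard(self, rng):
        df = pd.DataFrame(
            {"temperature": rng.uniform(7.5, 30.0, 200), "chl_a": rng.uniform(2, 40, 200)}
        )
        x, _ = transform_standardise(df, ["temperature", "chl_a"])
        assert np.abs(x.mean()).max() < 1e-12
        assert np.abs(x.std(ddof=1) - 1.0).max() < 1e-12

    def test_detection_limit_substitution(self):
        df = pd.DataFrame({"nh4": [0.02, 0.5, 1.0], "temperature": [10.0, 20.0, 30.0]})
        x, info = transform_standardise(df, ["nh4", "temperature"])
        # the sub-LOD value is lifted to 0.1 before the log transform
        raw = np.log(np.array([0.1, 0.5, 1.0]))
        expected = (raw - raw.mean()) / raw.std(ddof=1)
        np.testing.assert_allclose(x["nh4"].to_numpy(), expected, rtol=1e-12)
        assert info.detection_limits["nh4"] == 0.1

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"temperature": [12.0, 12.0, 12.0]})
        with pytest.raises(ValueError, match="temperature"):
            transform_standardise(df, ["temperature"])

    def test_nonpositive_value_names_column(self):
        df = pd.DataFrame({"turbidity": [-0.5, 1.0, 2.0]})
        with pytest.raises(ValueError, match="turbidity"):
            transform_standardise(df, ["turbidity"])

    def test_stored_transform_reproduces_matrix(self, rng):
        df = pd.DataFrame(
            {"temperature": rng.uniform(8, 30, 100), "po4": rng.uniform(0.01, 0.04, 100)}
        )
        x, info = transform_standardise(df, ["temperature", "po4"])
        np.testing.assert_allclose(info.apply(df).to_numpy(), x.to_numpy(), rtol=1e-12)


def simulate_gamma_glm(n, beta, shape, seed):
    rng = np.random.default_rng(seed)
    x = pd.DataFrame(rng.normal(size=(n, len(beta))), columns=[f"x{i}" for i in range(len(beta))])
    mu = np.exp(0.5 + x.to_numpy() @ np.asarray(beta))
    return mu * rng.gamma(shape, 1.0 / shape, n), x


class TestGammaGlm:
    def test_intercept_only_equals_log_mean(self, rng):
        phi = rng.gamma(5.0, 2.0, 400)
        res = fit_gamma_glm(phi, pd.DataFrame(index=range(400)))
        assert res.params["const"] == pytest.approx(np.log(phi.mean()), rel=1e-8)

    def test_coefficients_consistent_with_generating_model(self):
        """Bias of the ML estimate shrinks as n grows (family/link well
        specified): checked at n = 500 and n = 3360 over replicate seeds."""
        beta = [0.5, -0.3]
        errors = {}
        for n in (500, 3360):
            errs = []
            for seed in range(5):
                phi, x = simulate_gamma_glm(n, beta, shape=5.0, seed=seed)
                res = fit_gamma_glm(phi, x)
                errs.append(abs(res.params["x0"] - 0.5) + abs(res.params["x1"] + 0.3))
            errors[n] = np.mean(errs)
        assert errors[3360] < errors[500]
        assert errors[3360] < 0.05

    def test_rank_deficiency_reported(self, rng):
        a = rng.normal(size=100)
        x = pd.DataFrame({"a": a, "b": 2.0 * a})
        with pytest.raises(ValueError, match="rank deficient"):
            ElectronRequirementModel(np.exp(rng.normal(size=100)) + 0.1, x)

    def test_nonpositive_response_rejected(self, rng):
        x = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.raises(ValueError):
            ElectronRequirementModel(np.zeros(10), x)

    def test_summary_contains_coefficient_table(self, default_bootstrap):
        res = ElectronRequirementModel.from_dataframe(default_bootstrap).fit()
        text = res.summary()
        assert "temperature" in text and "AIC" in text and "VIF" in text

    def test_vif_low_on_screened_covariates(self, default_bootstrap):
        res = ElectronRequirementModel.from_dataframe(default_bootstrap).fit()
        assert res.vif.max() < 10.0


class TestRankAllSubmodels:
    def test_two_candidates_enumerate_four_subsets(self):
        phi, x = simulate_gamma_glm(400, [0.6, 0.0], shape=8.0, seed=3)
        ranking = rank_all_submodels(phi, x)
        assert len(ranking.table) == 4
        assert ranking.table["delta_aic"].iloc[0] == 0.0
        # the informative term is in the best subset; dropping the noise term
        # costs little (within the conventional 2-unit band)
        assert "x0" in ranking.best.terms
        with_noise = ranking.table.loc[ranking.table["terms"].map(set) == {"x0", "x1"}, "aic"].iloc[0]
        without = ranking.table.loc[ranking.table["terms"].map(set) == {"x0"}, "aic"].iloc[0]
        assert abs(with_noise - without) < 6.0

    def test_full_model_aic_matches_direct_fit(self):
        phi, x = simulate_gamma_glm(300, [0.4, -0.2, 0.1], shape=5.0, seed=1)
        ranking = rank_all_submodels(phi, x)
        direct = fit_gamma_glm(phi, x)
        full_row = ranking.table.loc[ranking.table["k"] == 3]
        assert full_row["aic"].iloc[0] == pytest.approx(direct.aic, rel=1e-10)

    def test_thirteen_candidates_enumerate_8192_subsets(self):
        phi, x = simulate_gamma_glm(200, [0.8] + [0.0] * 12, shape=10.0, seed=2)
        ranking = rank_all_submodels(phi, x)
        assert len(ranking.table) == 2**13
        assert ranking.failures == ()

    def test_selection_recovers_strong_true_terms(self, rng):
        """With three strong effects among six candidates, the AIC-best subset
        contains all three true terms in nearly every replicate."""
        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            phi, x = simulate_gamma_glm(
                1000, [0.5, -0.4, 0.3, 0.0, 0.0, 0.0], shape=5.0, seed=seed
            )
            ranking = rank_all_submodels(phi, x)
            if {"x0", "x1", "x2"} <= set(ranking.best.terms):
                hits += 1
        assert hits >= n_rep - 1

    def test_named_extracts_respect_exclusions(self, default_bootstrap):
        x, info = transform_standardise(default_bootstrap)
        sub = ["temperature", "nh4", "po4", "fraction_diatom", "fv_fm"]
        ranking = rank_all_submodels(
            default_bootstrap["phi_e_c"].to_numpy(), x[sub], transform=info
        )
        assert len(ranking.table) == 2**5
        m2 = ranking.best_without_nutrients
        assert not ({"nh4", "po4"} & set(m2.terms))
        m3 = ranking.best_without_nutrients_and_phyto
        assert not ({"nh4", "po4", "fraction_diatom"} & set(m3.terms))
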