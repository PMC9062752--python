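import numpy as np
import pandas as pd
import pytest

from methscore.association import (
    ModelSpec,
    SuiteConfig,
    fit_glm,
    mcfadden_r2,
    run_model_suite,
    sensitivity_suite,
)
from methscore.scoring import ThresholdSpec, build_score_set
from methscore.simulate import (
    CohortConfig,
    MddModel,
    SmokingConfounding,
    TraitConfig,
    simulate_cohort,
    simulate_mwas,
)


class TestMcFadden:
    def test_null_model_is_zero(self):
        assert mcfadden_r2(-10.0, -10.0) == 0.0

    def test_saturated_limit_is_one(self):
        assert mcfadden_r2(0.0, -10.0) == 1.0

    def test_degenerate_null_rejected(self):
        with pytest.raises(ValueError):
            mcfadden_r2(-1.0, 0.0)

    def test_six_observation_enumerated_likelihoods(self):
        """fit_glm's pseudo-R² matches explicitly computed log-likelihoods."""
        d = pd.DataFrame({"y": [0, 0, 1, 0, 1, 1], "x": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        res = fit_glm(ModelSpec("y", "binary-logistic", "x", (), "m"), d)
        # the fitted model's log-likelihood, recomputed from its own
        # probabilities via the Bernoulli formula
        import statsmodels.api as sm

        X = sm.add_constant(d[["x"]].to_numpy())
        fit = sm.Logit(d["y"].to_numpy(float), X).fit(disp=0)
        p = fit.predict()
        y = d["y"].to_numpy(float)
        ll_full = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        ll_null = 6 * np.log(0.5)  # 3 cases, 3 controls
        assert res.loglik_full == pytest.approx(ll_full, abs=1e-8)
        assert res.loglik_null == pytest.approx(ll_null, abs=1e-12)
        assert res.mcfadden_r2_full == pytest.approx(1 - ll_full / ll_null, abs=1e-8)


class TestFitGlm:
    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(0)
        d = pd.DataFrame({"y": rng.normal(0, 1, 50), "x": rng.normal(0, 1, 50)})
        d["z"] = 2 * d["x"]
        with pytest.raises(ValueError, match="collinear"):
            fit_glm(ModelSpec("y", "linear", "x", ("z",), "m"), d)

    def test_predictor_in_covariates_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("y", "linear", "x", ("x",), "m")

    def test_ordinal_two_levels_equals_logistic(self):
        rng = np.random.default_rng(1)
        n = 400
        x = rng.normal(0, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        d = pd.DataFrame({"y": y, "x": x})
        logit = fit_glm(ModelSpec("y", "binary-logistic", "x", (), "m"), d)
        ordinal = fit_glm(ModelSpec("y", "ordinal-logistic", "x", (), "m"), d)
        assert ordinal.beta == pytest.approx(logit.beta, abs=1e-6)
        assert ordinal.loglik_full == pytest.approx(logit.loglik_full, abs=1e-6)

    def test_incremental_r2_nonnegative(self, small_cohort, small_mwas):
        matrix, pheno, _ = small_cohort
        scores = build_score_set(matrix, [small_mwas], standardize=True)
        d = pheno.table.join(scores.get("bmi", "MW").rename("_ms"))
        res = fit_glm(
            ModelSpec("mdd", "binary-logistic", "_ms", ("age", "sex"), "m"), d
        )
        assert res.incremental_r2 >= -1e-10
        assert res.incremental_r2 == pytest.approx(
            res.mcfadden_r2_full - res.mcfadden_r2_reduced, abs=1e-14
        )

    def test_wald_and_lr_p_same_order_of_magnitude(self, small_cohort, small_mwas):
        from scipy import stats

        matrix, pheno, _ = small_cohort
        scores = build_score_set(matrix, [small_mwas], standardize=True)
        d = pheno.table.join(scores.get("bmi", "MW").rename("_ms"))
        res = fit_glm(ModelSpec("mdd", "binary-logistic", "_ms", ("age",), "m"), d)
        lr = 2 * (res.loglik_full - res.loglik_reduced)
        lr_p = stats.chi2.sf(lr, 1)
        assert 0.1 <= res.p_value / lr_p <= 10

    def test_separation_detected(self):
        d = pd.DataFrame({"y": [0.0] * 20 + [1.0] * 20, "x": list(range(40))})
        d["x"] = d["x"].astype(float)
        with pytest.raises(ValueError, match="[Ss]eparation|[Pp]erfect"):
            fit_glm(ModelSpec("y", "binary-logistic", "x", (), "m"), d)


@pytest.fixture(scope="module")
def suite_inputs():
    cfg = CohortConfig(
        n_samples=1200,
        n_cpgs=300,
        traits=(
            TraitConfig("bmi", 20, 0.3),
            TraitConfig("smoking", 25, 0.35, "ordinal", n_levels=4),
        ),
        mdd=MddModel(prevalence=0.25, trait_weights={"bmi": 0.5, "smoking": 0.6}),
        confounding=SmokingConfounding(
            exposure_prevalence=0.3,
            effect_size=0.8,
            n_affected_cpgs=30,
            shared_trait="bmi",
            n_shared_with=5,
        ),
        seed=21,
    )
    matrix, pheno, truth = simulate_cohort(cfg)
    recipes = [
        simulate_mwas(truth, "bmi", est_noise_sd=0.1, n_null_cpgs=50, seed=22),
        simulate_mwas(truth, "smoking", est_noise_sd=0.1, n_null_cpgs=50, seed=23),
    ]
    scores = build_score_set(
        matrix, recipes, (ThresholdSpec("MW"), ThresholdSpec("0.05", 0.05)),
        standardize=True,
    )
    config = SuiteConfig(
        base_covariates=("age", "sex"),
        lifestyle_covariates=("smoking_status", "pack_years"),
        trait_phenotypes={
            "bmi": ("bmi", "linear"),
            "smoking": ("smoking", "ordinal-logistic"),
        },
        smoking_trait="smoking",
        smoking_covariate="smoking_status",
    )
    return pheno, scores, config


class TestModelSuite:
    def test_rows_and_covariate_structure(self, suite_inputs):
        pheno, scores, config = suite_inputs
        table = run_model_suite(pheno, scores, config)
        # 2 traits x 2 thresholds x (3 models + validation)
        assert len(table) == 2 * 2 * 4
        assert set(table["model"]) == {"model1", "model2", "model3", "trait_validation"}
        m3 = table[table["model"] == "model3"]
        assert (m3["n"] <= table[table["model"] == "model1"]["n"].max()).all()

    def test_model2_r2_attenuates_under_mediation(self, suite_inputs):
        """MS affects MDD only through the phenotype here, so adjusting for
        the phenotype absorbs part of the MS signal."""
        pheno, scores, config = suite_inputs
        table = run_model_suite(pheno, scores, config)
        wide = table.pivot_table(
            index=["trait", "threshold"], columns="model", values="r2_incremental"
        )
        assert (wide["model2"] < wide["model1"]).mean() >= 0.5

    def test_sex_stratified_partition(self, suite_inputs):
        pheno, scores, config = suite_inputs
        strat = sensitivity_suite(pheno, scores, "sex_stratified", config)
        full = run_model_suite(pheno, scores, config)
        row_f = strat[(strat["stratum"] == "F") & (strat["model"] == "model2")].iloc[0]
        row_m = strat[(strat["stratum"] == "M") & (strat["model"] == "model2")].iloc[0]
        total = full[(full["model"] == "model2")].iloc[0]["n"]
        assert row_f["n"] + row_m["n"] == total

    def test_smoking_adjustment_spares_smoking_ms(self, suite_inputs):
        pheno, scores, config = suite_inputs
        adj = sensitivity_suite(pheno, scores, "smoking_adjusted_model1", config)
        smoking_rows = adj[adj["trait"] == "smoking"]
        assert (~smoking_rows["smoking_adjusted"]).all()
        other_rows = adj[adj["trait"] != "smoking"]
        assert other_rows["smoking_adjusted"].all()

    def test_confounded_ms_attenuated_by_smoking_adjustment(self):
        """An education-style MS confounded by smoking shrinks toward zero
        when smoking status enters model 1."""
        wins = 0
        n_rep = 50
        for rep in range(n_rep):
            cfg = CohortConfig(
                n_samples=2000,
                n_cpgs=150,
                traits=(TraitConfig("education", 11, 0.05, "ordinal", n_levels=5),),
                mdd=MddModel(prevalence=0.2, trait_weights={"education": 0.0}),
                confounding=SmokingConfounding(
                    exposure_prevalence=0.35,
                    effect_size=1.2,
                    n_affected_cpgs=40,
                    shared_trait="education",
                    n_shared_with=11,
                ),
                seed=3000 + rep,
            )
            matrix, pheno, truth = simulate_cohort(cfg)
            # smoking drives MDD directly in this scenario
            d = pheno.table.copy()
            liab = 1.0 * truth.smoking_exposed
            p = 1 / (1 + np.exp(-(-1.5 + liab)))
            rng = np.random.default_rng(5000 + rep)
            d["mdd"] = (rng.random(len(d)) < p).astype(float)
            mwas = simulate_mwas(truth, "education", est_noise_sd=0.05, seed=rep)
            scores = build_score_set(matrix, [mwas], (ThresholdSpec("MW"),), standardize=True)
            d = d.join(scores.get("education", "MW").rename("_ms"))
            unadj = fit_glm(ModelSpec("mdd", "binary-logistic", "_ms", ("age",), "u"), d)
            adj = fit_glm(
                ModelSpec("mdd", "binary-logistic", "_ms", ("age", "smoking_status"), "a"), d
            )
            wins += abs(adj.beta) < abs(unadj.beta)
        assert wins >= 0.9 * n_rep
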