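import warnings

import numpy as np
import pandas as pd
import pytest

from brockmet import simulate as sim
from brockmet.errors import InvalidInputError, VocabularyError
from brockmet.inference import (
    AnimalRecord,
    LinearModel,
    RandomInterceptModel,
    adjusted_means,
    dunnett_many_to_one,
    records_to_frame,
    stepwise_aic,
    tukey_contrasts,
    welch_anova,
)


class TestAnimalRecord:
    def test_vocabularies_enforced(self):
        with pytest.raises(VocabularyError):
            AnimalRecord("x", "M", "adult", "spring", 8.0)
        with pytest.raises(InvalidInputError):
            AnimalRecord("x", "M", "adult", "summer", -1.0)


class TestOls:
    def test_noiseless_linear_recovery(self, noiseless_cohort):
        df, truth = noiseless_cohort
        res = LinearModel(df, "rmr_kj_d ~ mass_kg + season").fit()
        assert res.params["Intercept"] == pytest.approx(truth["intercept"], rel=1e-9)
        assert res.params["mass_kg"] == pytest.approx(truth["mass_slope"], rel=1e-9)
        assert res.r2 == pytest.approx(1.0)

    def test_balanced_two_group_factor(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 5.0, 6.0, 7.0],
                           "g": ["a"] * 3 + ["b"] * 3})
        res = LinearModel(df, "y ~ g").fit()
        assert res.params["Intercept"] == pytest.approx(2.0)
        assert res.params["g[b]"] == pytest.approx(4.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            X = np.column_stack([np.ones(25), rng.normal(size=(25, 3))])
            y = rng.normal(size=25)
            df = pd.DataFrame({"y": y, "a": X[:, 1], "b": X[:, 2], "c": X[:, 3]})
            res = LinearModel(df, "y ~ a + b + c").fit()
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(res.params.to_numpy(), beta, rtol=1e-8)

    def test_matches_statsmodels(self, default_cohort):
        smf = pytest.importorskip("statsmodels.formula.api")
        _, df, _ = default_cohort
        res = LinearModel(df, "rmr_kj_d ~ mass_kg + season").fit()
        sm = smf.ols("rmr_kj_d ~ mass_kg + C(season, Treatment('summer'))", df).fit()
        np.testing.assert_allclose(
            np.sort(res.params.to_numpy()), np.sort(sm.params.to_numpy()), rtol=1e-9
        )
        assert res.r2 == pytest.approx(sm.rsquared, rel=1e-10)
        # statsmodels' AIC omits the variance parameter from k; differences agree
        assert res.aic == pytest.approx(sm.aic + 2.0, rel=1e-10)

    def test_slope_recovered_within_se_on_noisy_cohort(self):
        hits = 0
        for seed in range(40):
            recs, truth = sim.simulate_cohort(sim.CohortSimConfig(seed=seed))
            res = LinearModel(records_to_frame(recs), "rmr_kj_d ~ mass_kg + season").fit()
            se = res.bse["mass_kg"]
            hits += abs(res.params["mass_kg"] - truth["mass_slope"]) <= 2 * se
        assert hits >= 34  # ≈95% nominal coverage of ±2 SE

    def test_rank_deficiency_names_collinear_terms(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0, 5.0],
                           "a": [1.0, 2.0, 3.0, 4.0, 5.0],
                           "b": [2.0, 4.0, 6.0, 8.0, 10.0]})
        with pytest.raises(InvalidInputError, match="collinear"):
            LinearModel(df, "y ~ a + b")


class TestAdjustedMeans:
    def test_covariate_free_model_gives_raw_means(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 7.0, 8.0, 9.0],
                           "g": ["a"] * 3 + ["b"] * 3})
        res = LinearModel(df, "y ~ g").fit()
        am = adjusted_means(res, "g")
        assert am.means["a"][0] == pytest.approx(2.0)
        assert am.means["b"][0] == pytest.approx(8.0)

    def test_identical_mass_distributions_match_raw_means(self):
        mass = np.array([5.0, 7.0, 9.0, 11.0])
        df = pd.DataFrame({
            "y": np.concatenate([100 + 10 * mass, 200 + 10 * mass]),
            "mass_kg": np.tile(mass, 2),
            "g": ["a"] * 4 + ["b"] * 4,
        })
        res = LinearModel(df, "y ~ mass_kg + g").fit()
        am = adjusted_means(res, "g")
        assert am.means["a"][0] == pytest.approx(df[df.g == "a"].y.mean(), rel=1e-9)
        assert am.means["b"][0] == pytest.approx(df[df.g == "b"].y.mean(), rel=1e-9)

    def test_weighted_average_equals_fitted_grand_mean(self, default_cohort):
        _, df, _ = default_cohort
        res = LinearModel(df, "rmr_kj_d ~ mass_kg + season").fit()
        am = adjusted_means(res, "season")
        total = sum(am.means[lvl][0] * am.n_by_level[lvl] for lvl in am.means)
        grand = total / sum(am.n_by_level.values())
        assert grand == pytest.approx(res.fittedvalues.mean(), rel=1e-9)

    def test_coverage_of_true_level_means(self):
        # 2-SE interval around each season's adjusted mean covers the truth
        hits = tot = 0
        for seed in range(150):
            recs, truth = sim.simulate_cohort(sim.CohortSimConfig(seed=seed))
            df = records_to_frame(recs)
            res = LinearModel(df, "rmr_kj_d ~ mass_kg + season").fit()
            am = adjusted_means(res, "season")
            mbar = df["mass_kg"].mean()
            for lvl, (m, se) in am.means.items():
                true = truth["intercept"] + truth["mass_slope"] * mbar \
                    + truth["season_offsets"][lvl]
                hits += abs(m - true) <= 2 * se
                tot += 1
        assert hits / tot >= 0.93

    def test_nonpositive_evaluation_mass_rejected(self, default_cohort):
        _, df, _ = default_cohort
        res = LinearModel(df, "rmr_kj_d ~ mass_kg + season").fit()
        with pytest.raises(InvalidInputError):
            adjusted_means(res, "season", at_mass=-5.0)


class TestTukey:
    def test_two_level_family_equals_unadjusted(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0, 6.0, 8.0],
                           "g": ["a"] * 3 + ["b"] * 3})
        res = LinearModel(df, "y ~ g").fit()
        (c,) = tukey_contrasts(res, "g", mc_draws=20000, seed=9)
        assert c.p_adjusted == c.p_unadjusted

    def test_reproducible_given_seed(self, default_cohort):
        _, df, _ = default_cohort
        res = LinearModel(df, "rmr_kj_d ~ mass_kg + season").fit()
        a = tukey_contrasts(res, "season", mc_draws=20000, seed=123)
        b = tukey_contrasts(res, "season", mc_draws=20000, seed=123)
        assert [c.p_adjusted for c in a] == [c.p_adjusted for c in b]

    def test_adjusted_between_unadjusted_and_bonferroni(self, default_cohort):
        _, df, _ = default_cohort
        res = LinearModel(df, "rmr_kj_d ~ mass_kg + season").fit()
        cs = tukey_contrasts(res, "season", mc_draws=50000, seed=5)
        for c in cs:
            assert c.p_adjusted >= c.p_unadjusted
            assert c.p_adjusted <= min(1.0, 3.0 * c.p_unadjusted) + 0.01

    def test_low_draw_count_warns(self, default_cohort):
        _, df, _ = default_cohort
        res = LinearModel(df, "rmr_kj_d ~ mass_kg + season").fit()
        with pytest.warns(UserWarning, match="mc_draws"):
            tukey_contrasts(res, "season", mc_draws=1000, seed=5)


class TestDunnett:
    def test_identical_groups_p_near_one(self):
        g = {"ctrl": [5.0, 5.1, 4.9, 5.0], "a": [5.0, 5.1, 4.9, 5.0],
             "b": [5.05, 5.0, 4.95, 5.0]}
        for c in dunnett_many_to_one(g, control="ctrl", mc_draws=20000, seed=2):
            assert c.p_adjusted > 0.9

    def test_large_shift_detected(self):
        rng = np.random.default_rng(0)
        g = {"ctrl": rng.normal(0, 1, 10), "a": rng.normal(0, 1, 10),
             "b": rng.normal(10, 1, 10)}
        cs = {c.label: c for c in dunnett_many_to_one(g, control="ctrl",
                                                      mc_draws=50000, seed=2)}
        assert cs["b - ctrl"].p_adjusted < 0.001

    def test_two_groups_reduce_to_two_sample_t(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 12)
        (c,) = dunnett_many_to_one({"ctrl": a, "trt": b}, control="ctrl",
                                   mc_draws=20000, seed=2)
        t, p = stats.ttest_ind(b, a, equal_var=True)
        assert c.statistic == pytest.approx(t, rel=1e-9)
        assert c.p_adjusted == pytest.approx(p, rel=1e-9)

    def test_missing_control_rejected(self):
        with pytest.raises(InvalidInputError):
            dunnett_many_to_one({"a": [1.0, 2.0], "b": [2.0, 3.0]}, control="ctrl")


class TestWelch:
    def test_identical_means_f_zero_p_one(self):
        g = [[1.0, 2.0, 3.0], [2.5, 2.0, 1.5], [1.0, 3.0, 2.0]]
        res = welch_anova(g)
        assert res.f == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_equal_variance_balanced_agrees_with_classical_f(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, 10)
        # k = 2: the small-sample correction factor vanishes and Welch's F
        # equals the classical F exactly
        gs2 = [base + 0.0, base + 0.5]
        res2 = welch_anova(gs2)
        f2, _ = stats.f_oneway(*gs2)
        assert res2.f == pytest.approx(f2, rel=1e-9)
        # k = 3: they differ exactly by the correction factor
        # b = 1 + 2(k−2)/(k²−1)·λ with λ = Σ(1−w/Σw)²/(n−1)
        gs3 = [base + 0.0, base + 0.5, base + 1.0]
        res3 = welch_anova(gs3)
        f3, _ = stats.f_oneway(*gs3)
        lam = 3 * (1 - 1 / 3) ** 2 / 9
        b = 1 + 2 * (3 - 2) / (9 - 1) * lam
        assert res3.f == pytest.approx(f3 / b, rel=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        gs = [rng.normal(0, 1, 8), rng.normal(0.5, 2, 12), rng.normal(1, 0.5, 6)]
        res = welch_anova(gs)
        df = pd.DataFrame({"y": np.concatenate(gs),
                           "g": np.repeat(["a", "b", "c"], [8, 12, 6])})
        ref = pg.welch_anova(data=df, dv="y", between="g")
        assert res.f == pytest.approx(float(ref["F"][0]), rel=1e-9)
        assert res.df2 == pytest.approx(float(ref["ddof2"][0]), rel=1e-9)
        assert res.p == pytest.approx(float(ref["p_unc"][0]), rel=1e-9)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(InvalidInputError):
            welch_anova([[1.0, 1.0, 1.0], [2.0, 3.0, 4.0]])


class TestRandomIntercept:
    def test_zero_variance_ratio_profile_equals_ols(self):
        # at variance ratio 0 the GLS profile is exactly the OLS solution;
        # under a true-zero between-group variance the REML optimum sits at or
        # near that boundary and the fixed effects stay close to OLS
        rng = np.random.default_rng(5)
        n = 60
        df = pd.DataFrame({
            "x": rng.normal(0, 1, n),
            "g": np.repeat([f"g{i}" for i in range(15)], 4),
        })
        df["y"] = 2.0 + 0.5 * df["x"] + rng.normal(0, 1, n)
        model = RandomInterceptModel(df, "y ~ x", group="g")
        ols = LinearModel(df, "y ~ x").fit()
        beta0 = model._gls(0.0)[0]
        np.testing.assert_allclose(beta0, ols.params.to_numpy(), rtol=1e-10)
        mres = model.fit()
        np.testing.assert_allclose(mres.fe_params.to_numpy(),
                                   ols.params.to_numpy(), rtol=0.02)

    def test_matches_statsmodels_mixedlm(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        recs, _ = sim.simulate_anaesthesia_cohort(seed=3)
        df = records_to_frame(recs)
        mres = RandomInterceptModel(df, "rmr_kj_d ~ mass_kg + state",
                                    group="animal_id").fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = smf.mixedlm(
                "rmr_kj_d ~ mass_kg + C(state, Treatment('before'))",
                df, groups=df["animal_id"],
            ).fit(reml=True)
        np.testing.assert_allclose(np.sort(mres.fe_params.to_numpy()),
                                   np.sort(ref.fe_params.to_numpy()), rtol=1e-3)
        assert mres.loglik_reml == pytest.approx(ref.llf, abs=1e-5)
        assert mres.sigma2_resid == pytest.approx(ref.scale, rel=1e-3)

    def test_variance_components_recovered_at_scale(self):
        # scaled-up design: many groups, known variance components
        rng = np.random.default_rng(12)
        n_groups, per = 200, 3
        g = np.repeat(np.arange(n_groups), per)
        b = rng.normal(0, 2.0, n_groups)
        x = rng.normal(0, 1, n_groups * per)
        y = 1.0 + 0.5 * x + b[g] + rng.normal(0, 1.0, n_groups * per)
        df = pd.DataFrame({"y": y, "x": x, "g": [f"g{i}" for i in g]})
        res = RandomInterceptModel(df, "y ~ x", group="g").fit()
        assert res.sigma2_between == pytest.approx(4.0, rel=0.5)
        assert res.sigma2_resid == pytest.approx(1.0, rel=0.5)

    def test_reml_loglik_dominates_ols_boundary(self):
        recs, _ = sim.simulate_anaesthesia_cohort(seed=9)
        df = records_to_frame(recs)
        model = RandomInterceptModel(df, "rmr_kj_d ~ mass_kg + state",
                                     group="animal_id")
        res = model.fit()
        assert res.loglik_reml >= model._gls(0.0)[3] - 1e-9

    def test_shifting_one_group_raises_its_blup(self):
        recs, _ = sim.simulate_anaesthesia_cohort(seed=4)
        df = records_to_frame(recs)
        blup0 = RandomInterceptModel(df, "rmr_kj_d ~ mass_kg + state",
                                     group="animal_id").fit().random_effects["A01"]
        prev = blup0
        for shift in (200.0, 400.0):
            df2 = df.copy()
            df2.loc[df2.animal_id == "A01", "rmr_kj_d"] += shift
            cur = RandomInterceptModel(df2, "rmr_kj_d ~ mass_kg + state",
                                       group="animal_id").fit().random_effects["A01"]
            assert cur > prev
            prev = cur

    def test_all_singleton_groups_warns_and_reduces_to_ols(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"y": rng.normal(0, 1, 10), "x": rng.normal(0, 1, 10),
                           "g": [f"g{i}" for i in range(10)]})
        with pytest.warns(UserWarning, match="singleton"):
            model = RandomInterceptModel(df, "y ~ x", group="g")
        res = model.fit()
        ols = LinearModel(df, "y ~ x").fit()
        np.testing.assert_allclose(res.fe_params.to_numpy(),
                                   ols.params.to_numpy(), atol=1e-5)


class TestStepwiseAic:
    def test_forced_single_candidate_returned(self, default_cohort):
        _, df, _ = default_cohort
        res, trace = stepwise_aic(df, "rmr_kj_d", ["mass_kg"], include=("mass_kg",))
        assert res.model.terms == ["mass_kg"]

    def test_strong_effect_always_selected(self):
        for seed in range(10):
            recs, _ = sim.simulate_cohort(sim.CohortSimConfig(seed=seed))
            df = records_to_frame(recs)
            res, _ = stepwise_aic(df, "rmr_kj_d",
                                  ["mass_kg", "sex", "season", "age_class"])
            assert "mass_kg" in res.model.terms

    def test_pure_noise_covariates_mostly_excluded(self):
        rng = np.random.default_rng(21)
        kept = 0
        for _ in range(30):
            df = pd.DataFrame({
                "y": rng.normal(0, 1, 200),
                "a": rng.normal(0, 1, 200),
                "b": rng.normal(0, 1, 200),
            })
            res, _ = stepwise_aic(df, "y", ["a", "b"])
            kept += bool(res.model.terms)
        # AIC admits a pure-noise term with P(χ²₁ > 2) ≈ 0.157 each, so with two
        # candidates the intercept-only model is kept in ≈ 71% of runs
        assert kept <= 16

    def test_hierarchy_respected_for_interactions(self, default_cohort):
        _, df, _ = default_cohort
        res, trace = stepwise_aic(
            df, "rmr_kj_d", ["mass_kg", "season", "mass_kg:season"]
        )
        if "mass_kg:season" in res.model.terms:
            assert {"mass_kg", "season"} <= set(res.model.terms)

    def test_empty_candidates_rejected(self, default_cohort):
        _, df, _ = default_cohort
        with pytest.raises(InvalidInputError):
            stepwise_aic(df, "rmr_kj_d", [])
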