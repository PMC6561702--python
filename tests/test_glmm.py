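"""The binomial random-intercept model: fitting, predictions, summaries."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import special

import cliffwind as cw
from cliffwind.glmm import GlmmSpec, simulated_residual_uniformity


class TestCenterPredictors:
    def test_basic_centering(self):
        t = pd.DataFrame({"wind": [2.0, 4.0, 6.0], "turbulence": [0.1, 0.2, 0.3]})
        out, means = cw.center_predictors(t)
        assert np.allclose(out["wind_c"], [-2, 0, 2])
        assert means["wind"] == pytest.approx(4.0)
        assert "wind" in out.columns  # original retained

    def test_already_centred_unchanged(self):
        t = pd.DataFrame({"wind": [-1.0, 0.0, 1.0], "turbulence": [0.1, 0.2, 0.3]})
        out, means = cw.center_predictors(t)
        assert np.allclose(out["wind_c"], t["wind"])
        assert means["wind"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_column_warns(self):
        t = pd.DataFrame({"wind": [2.0, 4.0], "turbulence": [0.2, 0.2]})
        with pytest.warns(UserWarning, match="constant"):
            out, _ = cw.center_predictors(t)
        assert np.allclose(out["turbulence_c"], 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cw.center_predictors(pd.DataFrame({"wind": [], "turbulence": []}))


class TestFit:
    def test_centred_columns_have_mean_zero(self, obs_table):
        out, _ = cw.center_predictors(obs_table)
        assert abs(out["wind_c"].mean()) < 1e-12
        assert abs(out["turbulence_c"].mean()) < 1e-12

    def test_fit_matches_lme4(self, obs_table, tmp_path):
        """Laplace fit agrees with lme4::glmer on the same data."""
        centred, _ = cw.center_predictors(obs_table)
        centred["grp"] = centred["day"] + "|" + centred["colony"]
        csv = tmp_path / "obs.csv"
        centred.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv('{csv}')
            d$ledge <- relevel(factor(d$ledge), ref='large')
            d$species <- relevel(factor(d$species), ref='guillemot')
            d$height <- relevel(factor(d$height), ref='h4')
            m <- glmer(success ~ wind_c*ledge + turbulence_c*ledge + species
                       + height + (1|grp), data=d, family=binomial,
                       control=glmerControl(optimizer='bobyqa'))
            cat(fixef(m)['wind_c'], sqrt(unlist(VarCorr(m))),
                as.numeric(logLik(m)), sep='\\n')
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        wind_r, sd_r, ll_r = map(float, out.stdout.split())
        fit = cw.fit_landing_glmm(obs_table, quad_points=1)
        assert fit.coefficients["wind"] == pytest.approx(wind_r, abs=2e-3)
        assert fit.random_intercept_sd == pytest.approx(sd_r, abs=2e-3)
        assert fit.loglik == pytest.approx(ll_r, abs=0.01)

    def test_shift_invariance_of_wind(self, obs_table):
        """Adding a constant to wind changes only the centring mean."""
        f1 = cw.fit_landing_glmm(obs_table)
        shifted = obs_table.copy()
        shifted["wind"] = shifted["wind"] + 3.7
        f2 = cw.fit_landing_glmm(shifted)
        assert f2.centering["wind"] == pytest.approx(f1.centering["wind"] + 3.7)
        for k in f1.coefficients:
            assert f2.coefficients[k] == pytest.approx(f1.coefficients[k], abs=1e-8)
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-8)

    def test_zero_variance_truth_collapses_to_glm(self):
        """With no group effect the fit matches a plain logistic regression."""
        import statsmodels.api as sm
        from cliffwind.glmm import design_matrix

        t = cw.generate_observations(cw.SimulationConfig(
            n_attempts=3000, random_intercept_sd=0.0, seed=9))
        fit = cw.fit_landing_glmm(t)
        assert fit.random_intercept_sd < 0.1
        centred, means = cw.center_predictors(t)
        X, names, _, _ = design_matrix(t, fit.spec, means)
        glm = sm.GLM(t["success"].to_numpy(float), X,
                     family=sm.families.Binomial()).fit()
        for i, name in enumerate(names):
            assert fit.coefficients[name] == pytest.approx(glm.params[i], abs=1e-2)

    def test_aic_convention(self, glmm_fit):
        k = len(glmm_fit.coefficients) + 1
        assert glmm_fit.aic == pytest.approx(2 * k - 2 * glmm_fit.loglik)
        assert all(v > 0 for v in glmm_fit.se.values())

    def test_preconditions(self, obs_table):
        with pytest.raises(ValueError):
            cw.fit_landing_glmm(obs_table.iloc[:0])
        one_ledge = obs_table[obs_table["ledge"] == "large"]
        with pytest.raises(ValueError, match="ledge"):
            cw.fit_landing_glmm(one_ledge)


class TestPredict:
    def test_all_zero_fit_gives_half(self, glmm_fit):
        import copy
        flat = copy.deepcopy(glmm_fit)
        flat.coefficients = {k: 0.0 for k in flat.coefficients}
        p = cw.predict_success(flat, {"ledge": "small", "species": "razorbill",
                                      "height": "h1"}, 7.0)
        assert p == pytest.approx(0.5)

    def test_monotone_decreasing_in_wind(self, glmm_fit):
        prof = {"ledge": "long_narrow", "species": "guillemot", "height": "h4"}
        winds = np.linspace(0, 12, 25)
        p = cw.predict_success(glmm_fit, prof, winds)
        assert np.all(np.diff(p) < 0)
        assert np.all((p > 0) & (p < 1))

    def test_unknown_level_rejected(self, glmm_fit):
        with pytest.raises(ValueError, match="ledge"):
            cw.predict_success(glmm_fit, {"ledge": "cathedral"}, 5.0)

    def test_marginal_prediction_shrinks_extremes(self, glmm_fit):
        prof = {"ledge": "large", "species": "guillemot", "height": "h4"}
        p_pop = cw.predict_success(glmm_fit, prof, 0.0)
        p_marg = cw.predict_success(glmm_fit, prof, 0.0, marginal=True)
        assert p_pop > 0.5  # calm-wind baseline is a success
        assert 0.5 < p_marg < p_pop  # averaging over intercepts pulls inward


class TestAnodev:
    def test_noise_predictor_explains_nothing(self):
        t = cw.generate_observations(cw.SimulationConfig(
            n_attempts=2500, true_coefficients={"intercept": 0.3},
            random_intercept_sd=0.3, seed=13))
        tab = cw.anodev_table(t, GlmmSpec(terms=("wind",)))
        assert tab.loc[0, "deviance_explained_pct"] < 0.5

    def test_wind_dominates_when_only_wind_matters(self):
        t = cw.generate_observations(cw.SimulationConfig(
            n_attempts=2500,
            true_coefficients={"intercept": 0.8, "wind": -0.8},
            random_intercept_sd=0.2, seed=17))
        tab = cw.anodev_table(t, GlmmSpec(terms=("wind", "ledge", "species")))
        tab = tab.set_index("term")
        assert tab.loc["wind", "deviance_explained_pct"] > \
            5 * tab.loc["ledge", "deviance_explained_pct"]
        assert tab.loc["wind", "F"] == pytest.approx(
            tab.loc["wind", "deviance_drop"] / tab.loc["wind", "df"])

    def test_percentages_nonnegative_and_bounded(self, obs_table):
        tab = cw.anodev_table(obs_table)
        assert (tab["deviance_explained_pct"] > -1e-6).all()
        assert tab["deviance_explained_pct"].sum() <= 100.0


class TestR2:
    def test_degenerate_cases(self, glmm_fit):
        import copy
        flat = copy.deepcopy(glmm_fit)
        flat.coefficients = {k: 0.0 for k in flat.coefficients}
        flat.random_intercept_sd = 0.0
        flat.fixed_linear_predictor = np.zeros(100)
        assert cw.r2_nakagawa(flat) == (0.0, 0.0)
        nosd = copy.deepcopy(glmm_fit)
        nosd.random_intercept_sd = 0.0
        r2m, r2c = cw.r2_nakagawa(nosd)
        assert r2m == pytest.approx(r2c)

    def test_matches_generator_truth(self):
        """Fitted marginal R2 tracks the analytic value of the truth."""
        cfg = cw.SimulationConfig(n_attempts=6000, seed=21)
        t = cw.generate_observations(cfg)
        fit = cw.fit_landing_glmm(t)
        from cliffwind.synthetic import linear_predictor
        eta = linear_predictor(
            cfg.true_coefficients, t["wind"] - cfg.mean_wind,
            t["turbulence"] - cfg.turbulence_intensity,
            t["ledge"], t["species"], t["height"])
        var_f = float(np.var(eta))
        truth = var_f / (var_f + cfg.random_intercept_sd**2 + np.pi**2 / 3)
        r2m, r2c = cw.r2_nakagawa(fit)
        assert 0 <= r2m <= r2c <= 1
        assert r2m == pytest.approx(truth, abs=0.05)


class TestChiSquare:
    def test_identical_proportions_zero(self):
        res = cw.chi_square_preference([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 1

    def test_diagonal_table(self):
        res = cw.chi_square_preference([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 1 and res.n == 20

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            cw.chi_square_preference([[0, 0], [5, 5]])

    def test_species_ledge_preference_detected(self, obs_table):
        counts = pd.crosstab(obs_table["species"], obs_table["ledge"])
        res = cw.chi_square_preference(counts.to_numpy())
        assert res.df == 2 and res.p < 0.01  # generator builds in the bias


def test_simulated_residuals_uniform_on_well_specified_data(glmm_fit, obs_table):
    """PIT residuals from the true model family look uniform."""
    pvals = [simulated_residual_uniformity(glmm_fit, obs_table, n_sim=250,
                                           seed=s)[1] for s in range(6)]
    assert sum(p < 0.05 for p in pvals) <= 1
    resid, _ = simulated_residual_uniformity(glmm_fit, obs_table, seed=0)
    assert np.all((resid >= 0) & (resid <= 1))
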