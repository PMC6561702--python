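"""The attempt model: logistic curve, LogNormal mixing, geometric law."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cliffwind as cw
from cliffwind.landing import AttemptDistribution, LogisticLanding
from cliffwind.windfield import ScalingConstant


class TestLogisticCurve:
    @pytest.mark.parametrize("a, b, W, expected", [
        (1.0, 0.0, 7.3, 0.5),
        (1.0, 0.5, 0.0, 0.5),
        (1.0, 0.62, 10.0, 1.0 / (1.0 + math.exp(6.2))),
    ])
    def test_values(self, a, b, W, expected):
        assert cw.landing_prob_given_wind(LogisticLanding(a, b), W) == \
            pytest.approx(expected, rel=1e-12)

    def test_decreasing_iff_positive_b(self):
        W = np.linspace(0, 20, 50)
        assert np.all(np.diff(cw.landing_prob_given_wind(
            LogisticLanding(2.0, 0.4), W)) < 0)
        assert np.all(np.diff(cw.landing_prob_given_wind(
            LogisticLanding(2.0, -0.4), W)) > 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            LogisticLanding(0.0, 0.5)
        with pytest.raises(ValueError):
            cw.landing_prob_given_wind(LogisticLanding(1, 1), -1.0)


class TestCollapseFromFit:
    def test_all_zero_fit(self, glmm_fit):
        import copy
        flat = copy.deepcopy(glmm_fit)
        flat.coefficients = {k: 0.0 for k in flat.coefficients}
        m = cw.logistic_from_glmm(flat, {"ledge": "large", "species": "guillemot",
                                         "height": "h4"})
        assert m.a == pytest.approx(1.0) and m.b == pytest.approx(0.0)

    @pytest.mark.parametrize("ledge", ["large", "long_narrow", "small"])
    def test_identity_with_predict(self, glmm_fit, ledge):
        """The (a, b) curve equals the fit's prediction at every wind."""
        prof = {"ledge": ledge, "species": "razorbill", "height": "h2"}
        m = cw.logistic_from_glmm(glmm_fit, prof)
        rng = np.random.default_rng(5)
        W = rng.uniform(0, 15, size=100)
        p1 = cw.landing_prob_given_wind(m, W)
        p2 = cw.predict_success(glmm_fit, prof, W)
        assert np.max(np.abs(p1 - p2)) < 1e-12

    def test_b_combines_main_effect_and_interaction(self, glmm_fit):
        m = cw.logistic_from_glmm(glmm_fit, {"ledge": "small",
                                             "species": "guillemot",
                                             "height": "h4"})
        expected = -(glmm_fit.coefficients["wind"]
                     + glmm_fit.coefficients["wind:ledge[small]"])
        assert m.b == pytest.approx(expected, abs=1e-10)


class TestLogNormalMoments:
    def test_degenerate(self):
        wd = cw.lognormal_from_moments(10, 0)
        assert wd.s == 0.0 and wd.m == pytest.approx(math.log(10))

    def test_closed_form(self):
        wd = cw.lognormal_from_moments(10, 2)
        assert wd.s**2 == pytest.approx(math.log(1.04), rel=1e-12)
        assert wd.m == pytest.approx(2.282975, abs=1e-6)

    def test_sampling_moments(self):
        wd = cw.lognormal_from_moments(6, 1.8)
        rng = np.random.default_rng(8)
        x = wd.sample(10**6, rng)
        se_mean = x.std(ddof=1) / 1000
        assert abs(x.mean() - 6) < 3 * se_mean

    def test_rejects_nonpositive_mean(self):
        with pytest.raises(ValueError):
            cw.lognormal_from_moments(0.0, 1.0)

    @given(U=st.floats(0.2, 30), cv=st.floats(0, 2))
    @settings(max_examples=100, deadline=None)
    def test_roundtrip_moments(self, U, cv):
        wd = cw.lognormal_from_moments(U, cv * U)
        mean = math.exp(wd.m + wd.s**2 / 2)
        var = math.expm1(wd.s**2) * math.exp(2 * wd.m + wd.s**2)
        assert mean == pytest.approx(U, rel=1e-10)
        assert math.sqrt(max(var, 0.0)) == pytest.approx(cv * U, rel=1e-7, abs=1e-10)


class TestMeanLandingProb:
    def test_flat_curve_is_half(self):
        wd = cw.lognormal_from_moments(7, 3)
        assert cw.mean_landing_prob(LogisticLanding(1, 0), wd) == \
            pytest.approx(0.5, abs=1e-10)

    def test_point_mass_limit(self):
        m = LogisticLanding(2.0, 0.5)
        wd = cw.lognormal_from_moments(8.0, 8e-5)
        assert abs(cw.mean_landing_prob(m, wd)
                   - cw.landing_prob_given_wind(m, 8.0)) < 1e-6

    def test_mc_oracle_special_cases(self):
        wd = cw.lognormal_from_moments(5, 2)
        est, _ = cw.mean_landing_prob_mc(LogisticLanding(1, 0), wd, 1000, seed=1)
        assert est == pytest.approx(0.5, abs=1e-12)
        wd0 = cw.lognormal_from_moments(5, 0)
        m = LogisticLanding(1.5, 0.7)
        est, se = cw.mean_landing_prob_mc(m, wd0, 1000, seed=1)
        assert est == pytest.approx(cw.landing_prob_given_wind(m, 5.0))

    def test_decreasing_in_mean_wind(self):
        """For b > 0 at fixed TI, P falls as the mean wind rises."""
        m = LogisticLanding(3.0, 0.6)
        P = [cw.mean_landing_prob(m, cw.lognormal_from_moments(U, 0.2 * U))
             for U in np.linspace(0.5, 14, 15)]
        assert np.all(np.diff(P) < 0)


class TestAttemptDistribution:
    def test_half(self):
        att = cw.attempt_distribution(0.5)
        assert att.pmf(2) == pytest.approx(0.25)
        assert att.cumulative(3) == pytest.approx(0.875)
        assert att.expected_attempts == pytest.approx(2.0)

    def test_certain_success(self):
        att = cw.attempt_distribution(1.0)
        assert att.pmf(1) == 1.0 and att.expected_attempts == 1.0

    @given(P=st.floats(1e-6, 1.0), N=st.integers(1, 60))
    @settings(max_examples=100, deadline=None)
    def test_partial_sum_plus_tail_is_one(self, P, N):
        att = cw.attempt_distribution(P)
        n = np.arange(1, N + 1)
        total = att.pmf(n).sum() + (1 - P) ** N
        assert total == pytest.approx(1.0, abs=1e-12)
        assert att.cumulative(N) == pytest.approx(1 - (1 - P) ** N, abs=1e-12)

    def test_cumulative_monotone_in_n_and_P(self):
        n = np.arange(1, 30)
        c1 = cw.attempt_distribution(0.2).cumulative(n)
        c2 = cw.attempt_distribution(0.4).cumulative(n)
        assert np.all(np.diff(c1) > 0)
        assert np.all(c2 > c1)

    def test_invalid_P(self):
        for bad in (0.0, -0.1, 1.2):
            with pytest.raises(ValueError):
                cw.attempt_distribution(bad)


class TestAtSeaCurves:
    def test_collapse_with_unit_ratio_zero_ti(self):
        m = LogisticLanding(2.0, 0.5)
        winds = [0.0, 2.0, 5.0, 9.0]
        curves = cw.landing_curve_at_sea(m, 0.0, ScalingConstant(1.0), winds)
        assert np.allclose(curves["P"],
                           cw.landing_prob_given_wind(m, np.array(winds)))

    def test_monotone_decreasing_for_positive_b(self):
        m = LogisticLanding(2.0, 0.5)
        curves = cw.landing_curve_at_sea(m, 0.2, ScalingConstant(0.7),
                                         np.linspace(0.5, 16, 12))
        assert np.all(np.diff(curves["P"]) < 0)
        cum_cols = [c for c in curves.columns if c.startswith("cum_")]
        cum = curves[cum_cols].to_numpy()
        assert np.all(np.diff(cum, axis=1) >= 0)  # nondecreasing in attempts

    def test_rescaling_identity(self):
        m = LogisticLanding(1.5, 0.4)
        half = cw.landing_curve_at_sea(m, 0.2, ScalingConstant(0.5), [10.0])
        unit = cw.landing_curve_at_sea(m, 0.2, ScalingConstant(1.0), [5.0])
        assert half["P"].iloc[0] == pytest.approx(unit["P"].iloc[0], rel=1e-10)
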