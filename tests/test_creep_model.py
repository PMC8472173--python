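"""Unit and property tests for the tailored Burgers creep model."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from caulirheo.creep_model import (
    BurgersParams,
    FitError,
    durbin_watson,
    eval_burgers,
    fit_burgers,
    lack_of_fit,
    monte_carlo_ci,
    select_model_order,
)
from caulirheo.synthetic_data import LoadSchedule, gen_creep_curve


class TestEvalBurgers:
    def test_at_zero_time_returns_instantaneous_compliance(self, three_elem_params):
        assert eval_burgers(three_elem_params, 0.0) == pytest.approx(0.010)

    def test_long_time_asymptote_without_flow(self):
        p = BurgersParams(0.01, ((0.02, 100.0), (0.005, 10.0)), JN=0.0)
        assert eval_burgers(p, 1e9) == pytest.approx(0.01 + 0.02 + 0.005)

    def test_hand_evaluated_three_element_value(self):
        # independent term-by-term evaluation:
        # 0.010 + 0.020(1-e^-1) + 0.005(1-e^-10) + 0.002(1-e^-100) + 2e-5*100
        p = BurgersParams(0.010, ((0.020, 100.0), (0.005, 10.0), (0.002, 1.0)), 2e-5)
        assert eval_burgers(p, 100.0) == pytest.approx(0.031642, abs=5e-7)

    def test_negative_time_rejected(self, three_elem_params):
        with pytest.raises(ValueError):
            eval_burgers(three_elem_params, -1.0)

    @given(
        J0=st.floats(1e-4, 1.0),
        Ji=st.floats(0.0, 1.0),
        RTi=st.floats(0.1, 1e4),
        JN=st.floats(0.0, 1e-2),
    )
    def test_nondecreasing_in_time(self, J0, Ji, RTi, JN):
        p = BurgersParams(J0, ((Ji, RTi),), JN)
        t = np.linspace(0.0, 1200.0, 200)
        J = eval_burgers(p, t)
        assert J[0] == pytest.approx(J0)
        assert np.all(np.diff(J) >= -1e-15)


class TestParamValidation:
    def test_elements_canonicalized_by_relaxation_time(self):
        p = BurgersParams(0.01, ((0.02, 100.0), (0.005, 10.0)), 0.0)
        assert tuple(p.RTi) == (10.0, 100.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(J0=-0.01),
            dict(J0=0.01, elements=((-0.1, 10.0),)),
            dict(J0=0.01, elements=((0.1, -10.0),)),
            dict(J0=0.01, JN=-1e-6),
            dict(J0=0.01, elements=((0.1, 10.0), (0.2, 10.0))),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BurgersParams(**kwargs)


class TestDurbinWatson:
    def test_alternating_residuals(self):
        # sum of squared first differences 99*4 = 396 over sum of squares 100
        r = np.tile([1.0, -1.0], 50)
        assert durbin_watson(r) == pytest.approx(3.96)

    def test_constant_residuals_give_zero(self):
        assert durbin_watson(np.full(50, 0.3)) == pytest.approx(0.0)

    def test_white_noise_near_two(self):
        rng = np.random.default_rng(11)
        assert 1.8 < durbin_watson(rng.standard_normal(500)) < 2.2

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            durbin_watson(np.zeros(10))

    def test_too_few_residuals_rejected(self):
        with pytest.raises(ValueError):
            durbin_watson([1.0, -1.0])


class TestLackOfFit:
    def test_perfect_fit_is_zero(self):
        x = np.linspace(1.0, 2.0, 10)
        assert lack_of_fit(x, x, 3) == 0.0

    def test_hand_evaluated_uniform_relative_residual(self):
        # five relative residuals of 0.01, three parameters:
        # 100*sqrt(5*1e-4 / 2) = 1.5811
        fitted = np.full(5, 1.0)
        observed = fitted * (1 - 0.01)
        assert lack_of_fit(fitted, observed, 3) == pytest.approx(1.5811, abs=1e-3)

    def test_zero_fitted_value_rejected(self):
        with pytest.raises(ValueError):
            lack_of_fit(np.array([0.0, 1.0, 1.0, 1.0]), np.ones(4), 1)

    def test_requires_more_points_than_parameters(self):
        with pytest.raises(ValueError):
            lack_of_fit(np.ones(3), np.ones(3), 3)


class TestFitBurgers:
    def test_noiseless_round_trip_recovers_parameters(self, three_elem_params, schedule):
        curve = gen_creep_curve(three_elem_params, schedule, noise_cv=0.0)
        fit = fit_burgers(curve, m=3)
        x, xt = fit.params.to_array(), three_elem_params.to_array()
        assert np.max(np.abs(x - xt) / np.abs(xt)) < 1e-6
        assert fit.E_pct < 1e-6

    def test_degenerate_maxwell_line_fit(self, schedule):
        truth = BurgersParams(0.01, (), 2e-5)
        curve = gen_creep_curve(truth, schedule, noise_cv=0.0)
        fit = fit_burgers(curve, m=0)
        assert fit.params.J0 == pytest.approx(0.01, rel=1e-8)
        assert fit.params.JN == pytest.approx(2e-5, rel=1e-8)

    def test_robust_loss_round_trip(self, one_elem_params, schedule):
        curve = gen_creep_curve(one_elem_params, schedule, noise_cv=0.005, seed=3)
        fit = fit_burgers(curve, m=1, loss="robust")
        assert fit.params.J0 == pytest.approx(one_elem_params.J0, rel=0.05)
        assert fit.params.JN == pytest.approx(one_elem_params.JN, rel=0.2)

    def test_noisy_suite_lack_of_fit_below_two_percent(self, three_elem_params, schedule):
        curve = gen_creep_curve(three_elem_params, schedule, noise_cv=0.005, seed=21)
        fit = fit_burgers(curve, m=3)
        assert fit.E_pct < 2.0

    def test_optimum_no_worse_than_truth(self, three_elem_params, schedule):
        curve = gen_creep_curve(three_elem_params, schedule, noise_cv=0.005, seed=5)
        fit = fit_burgers(curve, m=3)
        t, J = curve.loading_time, curve.loading_compliance
        ssr_fit = np.sum((eval_burgers(fit.params, t) - J) ** 2)
        ssr_truth = np.sum((eval_burgers(three_elem_params, t) - J) ** 2)
        assert ssr_fit <= ssr_truth * (1 + 1e-9)

    def test_canonical_ordering_of_fitted_elements(self, three_elem_params, schedule):
        curve = gen_creep_curve(three_elem_params, schedule, noise_cv=0.005, seed=9)
        fit = fit_burgers(curve, m=3)
        assert np.all(np.diff(fit.params.RTi) > 0)

    def test_insufficient_points_rejected(self, three_elem_params):
        sched = LoadSchedule(hold_s=4.0, recovery_s=4.0, step_s=1.0)
        curve = gen_creep_curve(three_elem_params, sched)
        with pytest.raises(FitError):
            fit_burgers(curve, m=3)


class TestSelectModelOrder:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_three_element_truth_selected(self, three_elem_params, schedule, seed):
        curve = gen_creep_curve(three_elem_params, schedule, noise_cv=0.005, seed=seed)
        fit = select_model_order(curve, max_m=4)
        assert fit.m == 3

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_single_element_truth_selected_parsimoniously(self, one_elem_params, schedule, seed):
        curve = gen_creep_curve(one_elem_params, schedule, noise_cv=0.005, seed=seed)
        fit = select_model_order(curve, max_m=4)
        assert fit.m == 1

    def test_max_m_one_returns_that_fit(self, three_elem_params, schedule):
        curve = gen_creep_curve(three_elem_params, schedule, noise_cv=0.005, seed=0)
        assert select_model_order(curve, max_m=1).m == 1


class TestMonteCarloCI:
    def test_zero_residual_gives_point_intervals(self, one_elem_params, schedule):
        curve = gen_creep_curve(one_elem_params, schedule, noise_cv=0.0)
        fit = fit_burgers(curve, m=1)
        ci = monte_carlo_ci(fit, curve, n_sims=20, seed=0)
        for name, value in zip(fit.params.names, fit.params.to_array()):
            assert ci[name][0] == pytest.approx(value)
            assert ci[name][1] == pytest.approx(value)

    def test_point_estimate_inside_interval_and_deterministic(self, one_elem_params):
        sched = LoadSchedule(hold_s=600.0, recovery_s=600.0, step_s=5.0)
        curve = gen_creep_curve(one_elem_params, sched, noise_cv=0.005, seed=12)
        fit = fit_burgers(curve, m=1)
        ci1 = monte_carlo_ci(fit, curve, n_sims=60, seed=7)
        ci2 = monte_carlo_ci(fit, curve, n_sims=60, seed=7)
        assert ci1 == ci2
        for name, value in zip(fit.params.names, fit.params.to_array()):
            lo, hi = ci1[name]
            assert lo <= value <= hi
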