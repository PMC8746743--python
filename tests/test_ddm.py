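"""Closed-form DDM performance, first-passage sampling, and estimation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from rrddm.ddm import (
    DDMParams,
    EstimationError,
    InvalidParameterError,
    ddm_expected_performance,
    ddm_performance_derivatives,
    estimate_ddm,
    simulate_trial,
    simulate_trials,
    wiener_logpdf,
)

finite_drift = st.floats(min_value=0.05, max_value=4.0)
threshold = st.floats(min_value=0.3, max_value=5.0)


class TestClosedForm:
    def test_zero_drift_is_symmetric(self):
        perf = ddm_expected_performance(DDMParams(v=0.0, a=2.0))
        assert perf.er == pytest.approx(0.5)
        assert perf.dt == pytest.approx(1.0)  # a^2 / (4 sigma^2)

    def test_known_point(self):
        perf = ddm_expected_performance(DDMParams(v=1.0, a=2.0))
        assert perf.er == pytest.approx(1.0 / (1.0 + math.e ** 2), rel=1e-12)
        assert perf.dt == pytest.approx(math.tanh(1.0), rel=1e-12)

    def test_strong_drift_limit(self):
        perf = ddm_expected_performance(DDMParams(v=50.0, a=2.0))
        assert perf.er < 1e-10

    def test_continuous_through_zero_drift(self):
        lim = ddm_expected_performance(DDMParams(v=0.0, a=1.7))
        near = ddm_expected_performance(DDMParams(v=1e-7, a=1.7))
        assert near.er == pytest.approx(lim.er, abs=1e-6)
        assert near.dt == pytest.approx(lim.dt, rel=1e-6)

    @pytest.mark.parametrize(
        "field,kwargs",
        [("a", dict(v=1, a=0)), ("a", dict(v=1, a=-1)),
         ("sigma", dict(v=1, a=1, sigma=0)), ("ndt", dict(v=1, a=1, ndt=-0.1))],
    )
    def test_invalid_parameters_name_the_field(self, field, kwargs):
        with pytest.raises(InvalidParameterError, match=field):
            DDMParams(**kwargs)

    @given(v=finite_drift, a=threshold)
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_error_rate_decreases_with_drift_and_threshold(self, v, a):
        base = ddm_expected_performance(DDMParams(v=v, a=a)).er
        assert ddm_expected_performance(DDMParams(v=v * 1.1, a=a)).er < base
        assert ddm_expected_performance(DDMParams(v=v, a=a * 1.1)).er < base

    @given(v=finite_drift, a=threshold)
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_decision_time_increases_with_threshold(self, v, a):
        base = ddm_expected_performance(DDMParams(v=v, a=a)).dt
        assert ddm_expected_performance(DDMParams(v=v, a=a * 1.1)).dt > base

    @pytest.mark.parametrize("v,a", [(0.3, 0.8), (1.0, 2.0), (2.5, 1.2), (0.05, 3.0)])
    def test_derivatives_match_finite_differences(self, v, a):
        d = ddm_performance_derivatives(DDMParams(v=v, a=a))
        eps = 1e-6

        def er_of(v_, a_):
            return ddm_expected_performance(DDMParams(v=v_, a=a_)).er

        def dt_of(v_, a_):
            return ddm_expected_performance(DDMParams(v=v_, a=a_)).dt

        assert d["er_v"] == pytest.approx((er_of(v + eps, a) - er_of(v - eps, a)) / (2 * eps), rel=1e-5, abs=1e-9)
        assert d["er_a"] == pytest.approx((er_of(v, a + eps) - er_of(v, a - eps)) / (2 * eps), rel=1e-5, abs=1e-9)
        assert d["dt_v"] == pytest.approx((dt_of(v + eps, a) - dt_of(v - eps, a)) / (2 * eps), rel=1e-4, abs=1e-7)
        assert d["dt_a"] == pytest.approx((dt_of(v, a + eps) - dt_of(v, a - eps)) / (2 * eps), rel=1e-5, abs=1e-9)


class TestSampler:
    def test_deterministic_under_seed(self):
        p = DDMParams(v=1.2, a=1.5, ndt=0.3)
        assert simulate_trial(p, 123) == simulate_trial(p, 123)
        rt1, c1 = simulate_trials(p, 50, 9)
        rt2, c2 = simulate_trials(p, 50, 9)
        np.testing.assert_array_equal(rt1, rt2)
        np.testing.assert_array_equal(c1, c2)

    def test_rt_bounded_below_by_ndt(self):
        p = DDMParams(v=1.0, a=2.0, ndt=0.4)
        rt, _ = simulate_trials(p, 200, 4)
        assert np.all(rt >= p.ndt)

    def test_accuracy_matches_closed_form(self):
        p = DDMParams(v=1.0, a=2.0, ndt=0.4)
        n = 40_000
        rt, correct = simulate_trials(p, n, 2024)
        perf = ddm_expected_performance(p)
        se = math.sqrt(perf.er * (1 - perf.er) / n)
        assert correct.mean() == pytest.approx(1 - perf.er, abs=3 * se)
        dt = rt - p.ndt
        assert dt.mean() == pytest.approx(perf.dt, abs=3 * dt.std() / math.sqrt(n))

    def test_zero_drift_accuracy_is_chance(self):
        _, correct = simulate_trials(DDMParams(v=0.0, a=2.0), 40_000, 5)
        assert correct.mean() == pytest.approx(0.5, abs=3 * 0.5 / math.sqrt(40_000))


class TestEstimator:
    def test_recovers_generating_parameters(self):
        truth = DDMParams(v=1.5, a=1.8, ndt=0.35)
        rt, correct = simulate_trials(truth, 100_000, 7)
        est = estimate_ddm(pd.DataFrame({"rt": rt, "correct": correct}))
        assert 1.425 <= est.v <= 1.575  # within 5%
        assert 1.71 <= est.a <= 1.89
        assert est.ndt == pytest.approx(truth.ndt, abs=0.02)

    def test_ml_refinement_stays_consistent(self):
        truth = DDMParams(v=2.0, a=1.2, ndt=0.3)
        rt, correct = simulate_trials(truth, 5000, 11)
        est = estimate_ddm(pd.DataFrame({"rt": rt, "correct": correct}), refine=True)
        assert est.v == pytest.approx(truth.v, rel=0.1)
        assert est.a == pytest.approx(truth.a, rel=0.1)

    def test_error_shrinks_with_sample_size(self):
        truth = DDMParams(v=1.5, a=1.8, ndt=0.35)
        rel_err = {}
        for n in (1000, 100_000):
            rt, correct = simulate_trials(truth, n, 13)
            est = estimate_ddm(pd.DataFrame({"rt": rt, "correct": correct}))
            rel_err[n] = abs(est.v - truth.v) / truth.v + abs(est.a - truth.a) / truth.a
        assert rel_err[100_000] < rel_err[1000]

    @pytest.mark.parametrize(
        "correct_values,code",
        [(np.ones(200), "all_correct"), (np.zeros(200), "all_error"),
         (np.repeat([0, 1], 100), "chance_accuracy")],
    )
    def test_degenerate_accuracy_raises_with_code(self, correct_values, code):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"rt": rng.uniform(0.4, 1.0, 200), "correct": correct_values})
        with pytest.raises(EstimationError) as exc:
            estimate_ddm(df)
        assert exc.value.code == code

    def test_too_few_trials(self):
        df = pd.DataFrame({"rt": [0.5, 0.6], "correct": [1, 0]})
        with pytest.raises(EstimationError) as exc:
            estimate_ddm(df)
        assert exc.value.code == "too_few_trials"


class TestWienerDensity:
    @pytest.mark.parametrize("v,a", [(1.0, 2.0), (0.5, 1.0)])
    def test_density_integrates_to_closed_form_moments(self, v, a):
        perf = ddm_expected_performance(DDMParams(v=v, a=a))
        f_err = lambda t: math.exp(wiener_logpdf(t, v, a, False))
        f_cor = lambda t: math.exp(wiener_logpdf(t, v, a, True))
        er = quad(f_err, 1e-9, 100, limit=200)[0]
        mass = er + quad(f_cor, 1e-9, 100, limit=200)[0]
        mean_dt = quad(lambda t: t * (f_err(t) + f_cor(t)), 1e-9, 100, limit=200)[0]
        assert er == pytest.approx(perf.er, rel=1e-6)
        assert mass == pytest.approx(1.0, rel=1e-6)
        assert mean_dt == pytest.approx(perf.dt, rel=1e-6)
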