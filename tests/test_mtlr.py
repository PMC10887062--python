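"""MTLR: time grid, likelihood oracle, fitting, prediction."""

import numpy as np
import pytest
from scipy.special import logsumexp

from isdkit.exceptions import ValidationError
from isdkit.mtlr import (
    MTLRModel,
    MTLRParams,
    TimeGrid,
    build_time_grid,
    fit_mtlr,
    mtlr_objective,
    predict_survival_curve,
    select_lambda,
)
from isdkit.synthetic import StepEffect, default_config, generate_cohort

from conftest import ph_config


def brute_force_nll(params, x, t, event, grid, include_current=True):
    """Enumerate all m+1 monotone death sequences directly."""
    m = grid.m
    theta = params.W @ x + params.b
    log_u = np.array([theta[k - 1:].sum() for k in range(1, m + 2)])
    log_z = logsumexp(log_u)
    k = int(np.searchsorted(grid.tau, t, side="left")) + 1
    if event:
        return log_z - log_u[k - 1]
    lo = min(k if include_current else k + 1, m + 1)
    return log_z - logsumexp(log_u[lo - 1:])


class TestTimeGrid:
    def test_single_uncensored_record(self):
        grid = build_time_grid([5.0, 7.0], [1, 0])
        assert grid.m == 1
        assert grid.tau[0] == 5.0

    def test_hundred_events_quantile_grid(self):
        times = np.arange(1.0, 101.0)
        grid = build_time_grid(times, np.ones(100))
        assert grid.m == 10
        expected = np.quantile(times, np.arange(1, 11) / 11)
        np.testing.assert_allclose(grid.tau, expected)

    def test_ties_collapse_grid(self):
        grid = build_time_grid([3.0] * 9, np.ones(9))
        assert grid.m == 1

    def test_no_events_raises(self):
        with pytest.raises(ValidationError):
            build_time_grid([1.0, 2.0], [0, 0])

    def test_interval_convention_half_open(self):
        grid = TimeGrid(np.array([10.0, 20.0]))
        # event exactly at tau_k belongs to interval k
        assert grid.interval_index(10.0) == 1
        assert grid.interval_index(10.5) == 2
        assert grid.interval_index(25.0) == 3


class TestObjective:
    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(60):
            m = int(rng.integers(1, 9))
            tau = np.unique(np.sort(rng.uniform(0.5, 60.0, m)))
            grid = TimeGrid(tau)
            m = grid.m
            p = int(rng.integers(1, 4))
            params = MTLRParams(rng.normal(size=(m, p)), rng.normal(size=m), 0.0)
            x = rng.normal(size=p)
            t = float(rng.uniform(0.1, 70.0))
            event = int(rng.integers(0, 2))
            value, _ = mtlr_objective(params, x[None, :], [t], [event], grid)
            oracle = brute_force_nll(params, x, t, event, grid)
            assert abs(value - oracle) < 1e-10

    def test_gradient_matches_central_differences(self, rng):
        grid = TimeGrid(np.array([5.0, 12.0, 30.0]))
        m, p = 3, 2
        X = rng.normal(size=(4, p))
        times = [3.0, 8.0, 20.0, 50.0]
        events = [1, 0, 1, 0]
        for _ in range(10):
            theta0 = rng.normal(size=m * p + m)
            params = MTLRParams.unravel(theta0, m, p, 0.3)
            _, grad = mtlr_objective(params, X, times, events, grid)
            g = grad.ravel()
            h = 1e-5
            for i in rng.choice(theta0.size, size=4, replace=False):
                e = np.zeros_like(theta0)
                e[i] = h
                vp, _ = mtlr_objective(MTLRParams.unravel(theta0 + e, m, p, 0.3),
                                       X, times, events, grid)
                vm, _ = mtlr_objective(MTLRParams.unravel(theta0 - e, m, p, 0.3),
                                       X, times, events, grid)
                fd = (vp - vm) / (2 * h)
                assert abs(g[i] - fd) <= 1e-5 * max(1.0, abs(fd))

    def test_zero_params_uncensored_nll_is_log_m_plus_1(self):
        for m in (1, 3, 6):
            grid = TimeGrid(np.linspace(1.0, float(m), m))
            params = MTLRParams.zeros(m, 2)
            value, _ = mtlr_objective(params, np.zeros((1, 2)), [1.5], [1], grid)
            assert np.isclose(value, np.log(m + 1))

    def test_zero_params_censored_inside_interval_two(self):
        grid = TimeGrid(np.array([10.0, 20.0]))
        params = MTLRParams.zeros(2, 1)
        # censored at 15: consistent death intervals {2, 3} of 3 equiprobable
        value, _ = mtlr_objective(params, np.zeros((1, 1)), [15.0], [0], grid)
        assert np.isclose(value, -np.log(2.0 / 3.0))

    def test_hand_computed_single_patient(self):
        grid = TimeGrid(np.array([10.0, 20.0]))
        params = MTLRParams(np.array([[0.5], [-0.5]]), np.zeros(2), 0.0)
        # death in interval 1: log u = (0.0, -0.5, 0.0)
        value, _ = mtlr_objective(params, np.array([[1.0]]), [5.0], [1], grid)
        expected = -np.log(1.0 / (1.0 + np.exp(-0.5) + 1.0))
        assert np.isclose(value, expected, atol=1e-12)

    def test_numerically_convex_along_random_segments(self, rng):
        grid = TimeGrid(np.array([5.0, 15.0, 30.0, 50.0]))
        m, p = 4, 3
        X = rng.normal(size=(20, p))
        times = rng.uniform(1, 60, 20)
        events = rng.integers(0, 2, 20)

        def f(theta):
            return mtlr_objective(MTLRParams.unravel(theta, m, p, 0.1),
                                  X, times, events, grid)[0]

        for _ in range(100):
            a = rng.normal(size=m * p + m)
            b = rng.normal(size=m * p + m)
            assert f((a + b) / 2) <= (f(a) + f(b)) / 2 + 1e-9


class TestPrediction:
    def test_zero_params_closed_form_curve(self):
        grid = TimeGrid(np.array([5.0, 10.0, 15.0, 20.0]))
        model = MTLRModel(MTLRParams.zeros(4, 2), grid, ["a", "b"])
        curve = model.predict_curve(np.zeros(2))
        np.testing.assert_allclose(curve.probs, [1.0, 0.8, 0.6, 0.4, 0.2])
        assert np.isclose(curve.survival_at(10.0), 0.6)

    def test_curve_is_valid_probability(self, rng):
        grid = TimeGrid(np.sort(rng.uniform(1, 50, 6)))
        params = MTLRParams(rng.normal(size=(6, 3)), rng.normal(size=6), 1.0)
        model = MTLRModel(params, grid, ["a", "b", "c"])
        curve = model.predict_curve(rng.normal(size=3))
        assert curve.probs[0] == 1.0
        assert np.all(np.diff(curve.probs) <= 1e-12)
        assert np.all((curve.probs >= 0) & (curve.probs <= 1))

    def test_mismatched_covariate_length_raises(self):
        grid = TimeGrid(np.array([5.0]))
        model = MTLRModel(MTLRParams.zeros(1, 2), grid, ["a", "b"])
        with pytest.raises(ValidationError):
            model.predict_curve(np.zeros(3))


class TestFitting:
    def test_huge_lambda_collapses_to_marginal(self, rng):
        n = 150
        X = rng.normal(size=(n, 2))
        t = rng.exponential(20, n)
        ev = np.ones(n, dtype=int)
        grid = build_time_grid(t, ev)
        model = fit_mtlr(X, t, ev, grid, lam=1e6)
        assert np.max(np.abs(model.params.W)) < 1e-3
        c1 = model.predict_curve(X[0])
        c2 = model.predict_curve(X[1])
        np.testing.assert_allclose(c1.probs, c2.probs, atol=1e-3)

    def test_deterministic_fit(self, rng):
        X = rng.normal(size=(100, 2))
        t = rng.exponential(20, 100)
        ev = rng.integers(0, 2, 100)
        ev[:5] = 1
        grid = build_time_grid(t, ev)
        a = fit_mtlr(X, t, ev, grid, lam=1.0)
        b = fit_mtlr(X, t, ev, grid, lam=1.0)
        np.testing.assert_allclose(a.params.W, b.params.W, atol=1e-10)

    def test_null_model_recovery(self, rng):
        # no covariate signal: per-covariate mean effects stay near zero
        n = 800
        X = rng.normal(size=(n, 3))
        t = rng.exponential(25, n)
        ev = np.ones(n, dtype=int)
        grid = build_time_grid(t, ev)
        model = fit_mtlr(X, t, ev, grid, lam=1.0)
        assert np.all(np.abs(model.params.W.mean(axis=0)) < 0.05)
        assert np.mean(np.abs(model.params.W)) < 0.3

    def test_curves_cross_under_crossing_hazards(self):
        # strong protective-then-null treatment effect: treated curves start
        # higher but converge/cross relative to an untreated high-risk match
        cfg = default_config(
            n=1500, seed=33,
            effects={"treatment=Yes": StepEffect((18.0,), (-1.5, 1.0))},
        )
        cohort, _ = generate_cohort(cfg)
        from isdkit.cohort import encode_design

        design = encode_design(cohort)
        grid = build_time_grid(cohort.times, cohort.events)
        model = fit_mtlr(design.matrix, cohort.times, cohort.events, grid, lam=0.25)
        j = design.column_names.index("treatment=Yes")
        x_no = np.zeros(design.p)
        x_yes = np.zeros(design.p)
        x_yes[j] = 1.0
        s_no = model.predict_curve(x_no).probs[1:]
        s_yes = model.predict_curve(x_yes).probs[1:]
        diff = s_yes - s_no
        assert diff[0] > 0 and diff[-1] < 0  # ordering flips: curves cross


class TestLambdaSelection:
    def test_single_element_grid(self, rng):
        X = rng.normal(size=(50, 2))
        t = rng.exponential(20, 50)
        ev = np.ones(50, dtype=int)
        grid = build_time_grid(t, ev)
        assert select_lambda(X, t, ev, grid, [0.7]) == 0.7

    def test_strong_signal_prefers_weak_penalty(self):
        rng = np.random.default_rng(5)
        n = 1000
        X = rng.normal(size=(n, 2))
        beta = np.array([1.0, -1.0])
        T = rng.exponential(1 / (0.03 * np.exp(X @ beta)))
        C = rng.uniform(0, 60, n)
        obs, ev = np.minimum(T, C), (T <= C).astype(int)
        grid = build_time_grid(obs, ev)
        lam = select_lambda(X, obs, ev, grid, [1e-4, 1e6], seed=3)
        assert lam == 1e-4

    def test_reproducible_under_seed(self, rng):
        X = rng.normal(size=(120, 2))
        t = rng.exponential(20, 120)
        ev = np.ones(120, dtype=int)
        grid = build_time_grid(t, ev)
        a = select_lambda(X, t, ev, grid, [0.25, 4.0], seed=5)
        b = select_lambda(X, t, ev, grid, [0.25, 4.0], seed=5)
        assert a == b
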