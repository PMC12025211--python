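"""Bayesian-optimization machinery: encoding, objective, GP, EI, the loop."""

import numpy as np
import pytest

from ctbalance.bayesopt import (
    OBJECTIVE_CAP,
    DesignSpace,
    Variable,
    expected_improvement,
    gp_fit,
    objective_from_counts,
    optimize,
    propose_next,
)
from ctbalance.metrics import ConfusionCounts
from oracles import ei_monte_carlo, gp_posterior_oracle


def cc(tp, fp, fn, tn=0):
    return ConfusionCounts(*(np.array([0, v]) for v in (tp, fp, fn, tn)))


class TestEncoding:
    def test_log_axis_endpoints_and_midpoint(self):
        space = DesignSpace([Variable("lr", "log_continuous", 1e-4, 1e-2)])
        assert space.encode({"lr": 1e-4})[0] == pytest.approx(0.0)
        assert space.encode({"lr": 1e-2})[0] == pytest.approx(1.0)
        assert space.encode({"lr": 1e-3})[0] == pytest.approx(0.5)
        assert space.decode([0.5])["lr"] == pytest.approx(1e-3)

    def test_integer_decode_rounds(self):
        space = DesignSpace([Variable("bs", "integer", 10, 32)])
        assert space.decode([0.5])["bs"] == 21
        assert space.decode([0.0])["bs"] == 10
        assert space.decode([1.0])["bs"] == 32

    def test_roundtrip_identity(self):
        space = DesignSpace.hyperparameters()
        vals = space.decode(np.random.default_rng(0).uniform(size=space.dim))
        x = space.encode(vals)
        assert space.decode(x) == vals

    def test_out_of_bounds_rejected(self):
        space = DesignSpace([Variable("m", "continuous", 0.7, 0.99)])
        with pytest.raises(ValueError):
            space.encode({"m": 0.5})

    def test_hyperparameter_space_matches_declared_ranges(self):
        space = DesignSpace.hyperparameters()
        decoded = space.decode(np.zeros(space.dim))
        assert decoded["l2_regularization"] == pytest.approx(1e-4)
        assert decoded["batch_size"] == 10
        assert decoded["epochs"] == 5
        decoded = space.decode(np.ones(space.dim))
        assert decoded["gradient_threshold"] == 6
        assert decoded["momentum"] == pytest.approx(0.99)


class TestObjective:
    def test_perfect_classifier_floor(self):
        assert objective_from_counts(cc(10, 0, 0), [1]) == pytest.approx(1.0)

    def test_half_precision_recall(self):
        assert objective_from_counts(cc(5, 5, 5), [1]) == pytest.approx(2.0)

    def test_zero_tp_capped(self):
        assert objective_from_counts(cc(0, 3, 3), [1]) == OBJECTIVE_CAP
        assert objective_from_counts(cc(0, 0, 0), [1]) == OBJECTIVE_CAP

    def test_macro_vs_micro(self):
        counts = ConfusionCounts(np.array([0, 10, 2]), np.array([0, 0, 2]),
                                 np.array([0, 0, 2]), np.array([0, 0, 0]))
        macro = objective_from_counts(counts, [1, 2], average="macro")
        micro = objective_from_counts(counts, [1, 2], average="micro")
        f1_macro = 0.5 * (1.0 + 0.5)
        f1_micro = 24 / (24 + 2 + 2)
        assert macro == pytest.approx(1 / f1_macro)
        assert micro == pytest.approx(1 / f1_micro)


class TestGPSurrogate:
    @pytest.mark.parametrize("n_points", [5, 12, 20])
    def test_posterior_matches_linear_algebra_oracle(self, n_points):
        r = np.random.default_rng(n_points)
        X = r.uniform(size=(n_points, 2))
        y = ((X - 0.4) ** 2).sum(axis=1)
        cfg = {"length_scale": np.array([0.3, 0.4]), "constant_value": 1.5,
               "optimize": False}
        state = gp_fit(X, y, seed=1, kernel_config=cfg)
        Xq = r.uniform(size=(6, 2))
        mu_o, sd_o = gp_posterior_oracle(
            X, y, Xq, cfg["length_scale"], cfg["constant_value"], state.gp.alpha)
        mu, sd = state.predict(Xq)
        assert np.allclose(mu, mu_o, atol=1e-6)
        assert np.allclose(sd, sd_o, atol=1e-6)

    def test_interpolation_at_noise_floor(self):
        r = np.random.default_rng(7)
        X = r.uniform(size=(8, 1))
        y = np.sin(3 * X[:, 0])
        state = gp_fit(X, y, seed=0)
        mu, _ = state.predict(X)
        assert np.allclose(mu, y, atol=1e-5)

    def test_variance_far_from_data_approaches_prior(self):
        X = np.array([[0.0], [0.02]])
        y = np.array([1.0, 1.1])
        state = gp_fit(X, y, seed=0)
        _, sd_far = state.predict(np.array([[1.0]]))
        prior_sd = np.sqrt(state.gp.kernel_.k1.constant_value) * y.std()
        assert sd_far[0] == pytest.approx(prior_sd, rel=0.15)

    def test_needs_two_observations(self):
        with pytest.raises(ValueError):
            gp_fit(np.array([[0.5]]), np.array([1.0]))


class TestExpectedImprovement:
    def test_degenerate_sigma_zero(self):
        assert expected_improvement(np.array([0.7]), np.array([0.0]), 1.0)[0] == pytest.approx(0.3)
        assert expected_improvement(np.array([1.7]), np.array([0.0]), 1.0)[0] == 0.0

    def test_at_incumbent_mean_equals_phi0(self):
        ei = expected_improvement(np.array([2.0]), np.array([1.0]), 2.0)[0]
        assert ei == pytest.approx(0.3989422804, abs=1e-6)

    def test_closed_form_matches_monte_carlo(self):
        for i, (mu, sigma, inc) in enumerate([(0.0, 1.0, 0.0), (1.0, 0.5, 0.8),
                                              (-0.3, 2.0, 0.4)]):
            mc = ei_monte_carlo(mu, sigma, inc, n=10**6, seed=i)
            ei = expected_improvement(np.array([mu]), np.array([sigma]), inc)[0]
            assert ei == pytest.approx(mc, abs=2e-3)

    def test_nonnegative_everywhere(self, rng):
        mu = rng.normal(size=200)
        sigma = np.abs(rng.normal(size=200))
        assert np.all(expected_improvement(mu, sigma, 0.3) >= 0)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            expected_improvement(np.array([0.0]), np.array([-1.0]), 0.0)


class TestProposeAndOptimize:
    def test_proposal_within_bounds(self):
        space = DesignSpace.hyperparameters()
        r = np.random.default_rng(0)
        X = r.uniform(size=(8, space.dim))
        y = X.sum(axis=1)
        state = gp_fit(X, y, seed=0)
        values = propose_next(state, space, np.random.default_rng(1), n_candidates=256)
        space.encode(values)  # raises if out of bounds

    def test_proposal_beats_grid_on_1d(self):
        space = DesignSpace([Variable("x", "continuous", 0.0, 1.0)])
        r = np.random.default_rng(3)
        X = r.uniform(size=(10, 1))
        y = (X[:, 0] - 0.3) ** 2
        state = gp_fit(X, y, seed=0)
        grid = np.linspace(0, 1, 10**4)[:, None]
        mu, sd = state.predict(grid)
        from ctbalance.bayesopt import expected_improvement as ei_fn
        grid_best = ei_fn(mu, sd, state.incumbent_objective).max()
        values = propose_next(state, space, np.random.default_rng(5))
        mu_p, sd_p = state.predict(space.encode(values).reshape(1, -1))
        ei_p = ei_fn(mu_p, sd_p, state.incumbent_objective)[0]
        assert ei_p >= grid_best - 1e-9

    def test_optimize_finds_quadratic_minimum(self):
        space = DesignSpace([Variable("x", "continuous", 0.0, 1.0)])
        res = optimize(lambda v: (v["x"] - 0.3) ** 2, space, budget=30, seed=0)
        assert abs(res.best_values["x"] - 0.3) < 0.05
        assert len(res.history) == 30
        trace = res.incumbent_trace()
        assert np.all(np.diff(trace) <= 0)

    def test_objective_exceptions_recorded_as_cap(self):
        space = DesignSpace([Variable("x", "continuous", 0.0, 1.0)])

        def flaky(values):
            if values["x"] > 0.9:
                raise RuntimeError("boom")
            return values["x"]

        res = optimize(flaky, space, budget=12, n_init=6, seed=2)
        assert len(res.history) == 12
        failed = [o for o in res.history if o.error]
        assert all(o.objective == OBJECTIVE_CAP for o in failed)

    def test_budget_validation(self):
        space = DesignSpace([Variable("x", "continuous", 0.0, 1.0)])
        with pytest.raises(ValueError):
            optimize(lambda v: 0.0, space, budget=2, n_init=2, seed=0)


def test_planted_augmentation_ratio_recovery():
    """A synthetic objective minimized at d_a* = 0.35 inside the full
    detection design space is recovered within 0.05 in >= 4/5 seeded runs."""
    minima = np.array([1.02, 5.47])
    space = DesignSpace.detection(380, 10984, minima, with_cdv=True)

    def objective(values):
        return 1.0 + (values["d_a"] - 0.35) ** 2 * 10

    hits = 0
    for seed in range(5):
        res = optimize(objective, space, budget=30, n_init=10, seed=seed)
        hits += abs(res.best_values["d_a"] - 0.35) < 0.05
    assert hits >= 4
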