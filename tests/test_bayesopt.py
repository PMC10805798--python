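"""Bayesian optimiser: encoding, GP posterior against a dense oracle,
expected improvement, over-exploitation control and the full loop."""

import math

import numpy as np
import pytest

from myotune.bayesopt import (
    AcquisitionConfig,
    Dimension,
    Evaluation,
    GPSurrogate,
    HyperParams,
    SearchSpace,
    TimingModel,
    check_overexploitation,
    decode_point,
    default_search_space,
    encode_point,
    escape_overexploitation,
    expected_improvement,
    expected_improvement_per_second,
    fit_gp,
    incumbent_best,
    propose_next,
    run_bayesopt,
)
from myotune.exceptions import ConfigError, DataError


def dense_gp_oracle(X, y, U, length_scales, amplitude, noise):
    """Independent dense-linear-algebra GP posterior (standardised targets)."""
    ls = np.asarray(length_scales, dtype=float)

    def k(a, b):
        r = math.sqrt((((a - b) / ls) ** 2).sum())
        s = math.sqrt(5.0) * r
        return amplitude**2 * (1 + s + s * s / 3.0) * math.exp(-s)

    ym, ys = y.mean(), y.std() if y.std() > 1e-12 else 1.0
    z = (y - ym) / ys
    K = np.array([[k(a, b) for b in X] for a in X]) + (noise**2 + 1e-10) * np.eye(len(X))
    Ki = np.linalg.inv(K)
    mus, sigmas = [], []
    for u in np.atleast_2d(U):
        ks = np.array([k(u, b) for b in X])
        mus.append(ym + ys * float(ks @ Ki @ z))
        var = k(u, u) - float(ks @ Ki @ ks)
        sigmas.append(ys * math.sqrt(max(var, 0.0)))
    return np.array(mus), np.array(sigmas)


def unit_space(d=2):
    return SearchSpace(tuple(Dimension(f"u{i}", 0.0, 1.0) for i in range(d)))


class TestEncoding:
    def test_log_scale_bound_mapping(self):
        space = default_search_space()
        u = encode_point(HyperParams(1e-4, 0.8, 1e-10, 1), space)
        assert np.allclose(u, 0.0)
        u = encode_point(HyperParams(1e-2, 0.98, 1e-1, 3), space)
        assert np.allclose(u, 1.0)

    def test_linear_midpoint(self):
        space = default_search_space()
        u = encode_point(HyperParams(1e-3, 0.89, 1e-5, 2), space)
        assert u[1] == pytest.approx((0.89 - 0.8) / (0.98 - 0.8))

    def test_roundtrip_identity(self):
        space = default_search_space()
        for hp in [
            HyperParams(3e-3, 0.85, 1e-4, 2),
            HyperParams(1e-4, 0.98, 1e-10, 1),
            HyperParams(9.99e-3, 0.8, 0.05, 3),
        ]:
            back = decode_point(encode_point(hp, space), space)
            assert back["section_depth"] == hp.section_depth
            assert back["learning_rate"] == pytest.approx(hp.learning_rate, rel=1e-12)
            assert back["momentum"] == pytest.approx(hp.momentum, rel=1e-12)
            assert back["l2_strength"] == pytest.approx(hp.l2_strength, rel=1e-12)

    def test_out_of_bounds_rejected(self):
        space = default_search_space()
        with pytest.raises(ConfigError):
            encode_point(HyperParams(0.5, 0.9, 1e-4, 2), space)


class TestGPSurrogate:
    def test_posterior_matches_dense_oracle(self):
        rng = np.random.default_rng(42)
        for n in (2, 4, 8):
            X = rng.random((n, 3))
            y = rng.random(n)
            ls = rng.uniform(0.2, 1.0, 3)
            amp, noise = 1.2, 0.15
            gp = GPSurrogate(X, y, ls, amp, noise)
            U = rng.random((6, 3))
            mu, sf = gp.posterior(U)
            mu_o, sf_o = dense_gp_oracle(X, y, U, ls, amp, noise)
            assert np.allclose(mu, mu_o, atol=1e-8)
            assert np.allclose(sf, sf_o, atol=1e-8)

    def test_single_point_interpolation_limit(self):
        space = unit_space(1)
        evals = [Evaluation({"u0": 0.4}, 0.7), Evaluation({"u0": 0.6}, 0.9)]
        gp = fit_gp(evals, space, seed=0)
        tiny = GPSurrogate(gp.X, gp.y, gp.length_scales, gp.amplitude, 1e-8)
        mu, _ = tiny.posterior(np.array([[0.4], [0.6]]))
        assert np.allclose(mu, [0.7, 0.9], atol=1e-6)

    def test_reversion_to_prior_far_from_data(self):
        X = np.array([[0.01, 0.01]])
        gp = GPSurrogate(X, np.array([0.3]), np.array([0.02, 0.02]), 1.5, 0.01)
        mu, sf = gp.posterior(np.array([[0.99, 0.99]]))
        assert mu[0] == pytest.approx(gp.ym, abs=1e-6)
        assert sf[0] == pytest.approx(gp.ys * gp.amplitude, rel=1e-6)

    def test_fit_requires_two_finite_points(self):
        space = unit_space(1)
        with pytest.raises(DataError):
            fit_gp([Evaluation({"u0": 0.5}, 0.1)], space)

    def test_fit_is_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        space = unit_space(2)
        evals = [
            Evaluation({"u0": a, "u1": b}, float(a + b))
            for a, b in rng.random((6, 2))
        ]
        g1 = fit_gp(evals, space, seed=5)
        g2 = fit_gp(evals, space, seed=5)
        assert np.array_equal(g1.length_scales, g2.length_scales)
        assert g1.amplitude == g2.amplitude and g1.noise == g2.noise


class TestIncumbent:
    def test_near_noiseless_single_minimum(self):
        X = np.array([[0.2], [0.8]])
        gp = GPSurrogate(X, np.array([0.4, 0.6]), np.array([0.3]), 1.0, 1e-6)
        assert incumbent_best(gp) == pytest.approx(0.4, abs=1e-4)

    def test_noisy_duplicates_shrink_toward_mean(self):
        # two observations at the same x with y = 0.1 and 0.3: the posterior
        # mean there lies strictly between them (GP shrinkage)
        X = np.array([[0.5], [0.5]])
        gp = GPSurrogate(X, np.array([0.1, 0.3]), np.array([0.3]), 1.0, 0.3)
        inc = incumbent_best(gp)
        assert 0.1 < inc < 0.3

    def test_min_monotonicity_when_adding_lower_point(self):
        X = np.array([[0.2], [0.8]])
        y = np.array([0.5, 0.6])
        gp = GPSurrogate(X, y, np.array([0.25]), 1.0, 0.01)
        inc1 = incumbent_best(gp)
        X2 = np.vstack([X, [[0.5]]])
        y2 = np.append(y, 0.1)
        gp2 = GPSurrogate(X2, y2, np.array([0.25]), 1.0, 0.01)
        assert incumbent_best(gp2) <= inc1 + 1e-9


class TestExpectedImprovement:
    def test_deterministic_improvement_limit(self):
        assert expected_improvement(0.1, 0.0, 0.3) == pytest.approx(0.2)

    def test_no_improvement_limit(self):
        assert expected_improvement(1.3, 0.0, 0.3) == 0.0

    def test_standard_normal_value(self):
        # mu = best, sigma = 1: EI = phi(0) = 0.3989...
        assert expected_improvement(0.5, 1.0, 0.5) == pytest.approx(0.3989, abs=0.002)

    def test_matches_monte_carlo_definition(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            mu = rng.uniform(-1, 1)
            sigma = rng.uniform(0.05, 1.5)
            best = rng.uniform(-1, 1)
            draws = rng.normal(mu, sigma, 400_000)
            mc = np.maximum(best - draws, 0.0).mean()
            assert expected_improvement(mu, sigma, best) == pytest.approx(
                mc, abs=3e-3
            )

    def test_negative_sigma_rejected(self):
        with pytest.raises(DataError):
            expected_improvement(0.0, -0.1, 0.0)


class TestEIpS:
    def _evals(self, costs):
        rng = np.random.default_rng(3)
        return [
            Evaluation({"u0": float(u)}, float(u**2), cost_s=c)
            for u, c in zip(rng.random(len(costs)), costs)
        ]

    def test_ratio(self):
        space = unit_space(1)
        evals = self._evals([2.0] * 6)
        gp = fit_gp(evals, space, seed=0)
        timing = TimingModel(evals, space, seed=0)
        U = np.array([[0.3]])
        eips = expected_improvement_per_second(U, gp, timing, incumbent_best(gp))
        mu, sf = gp.posterior(U)
        ei = expected_improvement(mu[0], sf[0], incumbent_best(gp))
        assert eips[0] == pytest.approx(ei / timing.mu_s(U)[0])

    def test_constant_cost_preserves_ei_ranking(self):
        space = unit_space(1)
        evals = self._evals([2.0] * 6)
        gp = fit_gp(evals, space, seed=0)
        timing = TimingModel(evals, space, seed=0)
        U = np.linspace(0, 1, 17)[:, None]
        best = incumbent_best(gp)
        mu, sf = gp.posterior(U)
        ei = np.asarray(expected_improvement(mu, sf, best))
        eips = expected_improvement_per_second(U, gp, timing, best)
        assert np.array_equal(np.argsort(ei), np.argsort(eips))

    def test_doubling_costs_halves_eips(self):
        space = unit_space(1)
        evals1 = self._evals([1.5] * 8)
        evals2 = [Evaluation(e.x, e.y, e.cost_s * 2) for e in evals1]
        gp = fit_gp(evals1, space, seed=0)
        best = incumbent_best(gp)
        t1 = TimingModel(evals1, space, seed=0)
        t2 = TimingModel(evals2, space, seed=0)
        U = np.array([[0.2], [0.7]])
        a = expected_improvement_per_second(U, gp, t1, best)
        b = expected_improvement_per_second(U, gp, t2, best)
        assert np.allclose(b, a / 2.0, rtol=1e-3)


class TestOverExploitation:
    def test_threshold_rule_matches_definition(self):
        X = np.linspace(0.4, 0.6, 8)[:, None]
        y = 0.2 + 0.1 * X[:, 0]
        gp = GPSurrogate(X, y, np.array([0.3]), 1.0, 0.5)
        cfg = AcquisitionConfig(t_sigma=0.5)
        for u in (0.5, 0.05, 0.95):
            _, sf = gp.posterior(np.array([[u]]))
            expected = bool(sf[0] < gp.noise_sigma * cfg.t_sigma)
            assert check_overexploitation(np.array([u]), gp, cfg) == expected

    def test_huge_t_sigma_always_triggers(self):
        X = np.array([[0.1], [0.9]])
        gp = GPSurrogate(X, np.array([0.1, 0.9]), np.array([0.3]), 1.0, 0.2)
        cfg = AcquisitionConfig(t_sigma=1e6)
        for u in np.linspace(0, 1, 5):
            assert check_overexploitation(np.array([u]), gp, cfg)

    def test_tiny_t_sigma_never_triggers(self):
        X = np.array([[0.0], [1.0]])
        gp = GPSurrogate(X, np.array([0.0, 1.0]), np.array([0.5]), 1.0, 0.3)
        cfg = AcquisitionConfig(t_sigma=1e-9)
        for u in np.linspace(0, 1, 7):
            assert not check_overexploitation(np.array([u]), gp, cfg)

    def test_escape_identity_at_iteration_one(self):
        X = np.array([[0.1], [0.9]])
        gp = GPSurrogate(X, np.array([0.2, 0.8]), np.array([0.4]), 1.0, 0.1)
        esc = escape_overexploitation(gp, 1)
        assert np.array_equal(esc.length_scales, gp.length_scales)

    def test_escape_raises_midpoint_variance(self):
        X = np.array([[0.2], [0.8]])
        gp = GPSurrogate(X, np.array([0.1, 0.5]), np.array([0.5]), 1.0, 0.05)
        esc = escape_overexploitation(gp, 5)
        _, s0 = gp.posterior(np.array([[0.5]]))
        _, s1 = esc.posterior(np.array([[0.5]]))
        assert s1[0] >= s0[0]

    def test_repeated_escape_is_multiplicative(self):
        X = np.array([[0.1], [0.9]])
        gp = GPSurrogate(X, np.array([0.2, 0.8]), np.array([0.4]), 1.0, 0.1)
        twice = escape_overexploitation(escape_overexploitation(gp, 2), 3)
        assert np.allclose(twice.length_scales, gp.length_scales / 6.0)
        assert np.allclose(
            1.0 / twice.theta[:-1], (1.0 / gp.theta[:-1]) / 6.0
        )


class TestProposeAndLoop:
    def test_proposal_feasible_and_deterministic(self):
        space = default_search_space()
        rng = np.random.default_rng(0)
        evals = [
            Evaluation(space.decode(u), float(u.sum())) for u in rng.random((5, 4))
        ]
        gp = fit_gp(evals, space, seed=1)
        cfg = AcquisitionConfig(seed=9, n_candidates=256)
        a = propose_next(gp, space, cfg)
        b = propose_next(gp, space, cfg)
        assert a == b
        assert space.contains(a)
        assert isinstance(a["section_depth"], int)

    def test_quadratic_proposal_lands_in_interior(self):
        space = unit_space(1)
        evals = [
            Evaluation({"u0": 0.0}, (0.0 - 0.3) ** 2),
            Evaluation({"u0": 1.0}, (1.0 - 0.3) ** 2),
            Evaluation({"u0": 0.55}, (0.55 - 0.3) ** 2),
        ]
        gp = fit_gp(evals, space, seed=0)
        prop = propose_next(gp, space, AcquisitionConfig(seed=1, n_candidates=512))
        assert 0.0 < prop["u0"] < 1.0
        assert prop["u0"] not in (0.0, 0.55, 1.0)

    def test_budget_equal_to_init_design_is_degenerate(self):
        space = unit_space(2)
        calls = []

        def obj(x):
            calls.append(x)
            return x["u0"]

        trace = run_bayesopt(obj, space, budget=4, seed=0, init_design=4)
        assert len(trace.evaluations) == 4 == len(calls)
        assert trace.best_y == min(e.y for e in trace.evaluations)

    def test_budget_below_init_design_rejected(self):
        with pytest.raises(ConfigError):
            run_bayesopt(lambda x: 0.0, unit_space(1), budget=2, init_design=4)

    def test_replay_is_identical(self):
        space = unit_space(2)

        def obj(x):
            return (x["u0"] - 0.4) ** 2 + (x["u1"] - 0.6) ** 2

        t1 = run_bayesopt(obj, space, budget=8, seed=3)
        t2 = run_bayesopt(obj, space, budget=8, seed=3)
        assert [e.x for e in t1.evaluations] == [e.x for e in t2.evaluations]
        assert [e.y for e in t1.evaluations] == [e.y for e in t2.evaluations]

    def test_best_so_far_non_increasing(self):
        space = unit_space(2)

        def obj(x):
            return (x["u0"] - 0.25) ** 2 + (x["u1"] - 0.75) ** 2

        trace = run_bayesopt(obj, space, budget=10, seed=1)
        bsf = trace.best_so_far
        assert np.all(np.diff(bsf) <= 0.0 + 1e-15)

    def test_failed_evaluations_get_penalty_targets(self):
        space = unit_space(1)
        state = {"n": 0}

        def obj(x):
            state["n"] += 1
            if state["n"] == 6:
                raise RuntimeError("diverged")
            return x["u0"]

        trace = run_bayesopt(obj, space, budget=8, seed=0)
        failed = [e for e in trace.evaluations if e.failed]
        assert len(failed) == 1
        ok_ys = [e.y for e in trace.evaluations if not e.failed]
        assert failed[0].y > max(ok_ys)

    def test_overexploitation_rule_reduces_revisits(self):
        # seed a near-zero-variance region: with the rule enabled the
        # proposer should revisit the incumbent's neighbourhood less often
        space = unit_space(1)
        X = np.linspace(0.45, 0.55, 6)[:, None]
        y = 0.2 + 0.001 * (X[:, 0] - 0.5) ** 2
        evals = [Evaluation({"u0": float(u)}, float(t)) for u, t in zip(X[:, 0], y)]
        gp = GPSurrogate(X, y, np.array([0.3]), 1.0, 0.2)

        def revisits(enabled: bool) -> int:
            count = 0
            for seed in range(20):
                cfg = AcquisitionConfig(
                    seed=seed, n_candidates=256,
                    t_sigma=0.5 if enabled else 1e-12,
                )
                prop = propose_next(gp, space, cfg, iteration=8)
                if 0.4 <= prop["u0"] <= 0.6:
                    count += 1
            return count

        assert revisits(True) <= revisits(False)
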