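"""Unit and property tests for the Archimedes optimizer."""

import math

import numpy as np
import pytest

from cardiovault.aoa import (
    AOAConfig,
    MaterialObject,
    compute_acceleration,
    density_factor,
    exploitation_move,
    exploration_move,
    initialize_population,
    normalize_acceleration,
    optimize,
    select_flag,
    step,
    transfer_operator,
    update_density_volume,
)


def _obj(pos, den, vol, acl, fit=0.0):
    return MaterialObject(
        np.asarray(pos, float), np.asarray(den, float),
        np.asarray(vol, float), np.asarray(acl, float), fit,
    )


class TestSchedules:
    def test_transfer_operator_values(self):
        assert transfer_operator(100, 100) == pytest.approx(1.0)
        assert transfer_operator(50, 100) == pytest.approx(math.exp(-0.5))
        # T -> 0 limit approaches exp(-1)
        assert math.exp((1 - 10**6) / 10**6) == pytest.approx(math.exp(-1), rel=1e-4)

    def test_transfer_operator_strictly_increasing(self):
        vals = [transfer_operator(t, 50) for t in range(1, 51)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(1.0)

    @pytest.mark.parametrize("dialect", ["paper", "canonical"])
    def test_density_factor_decreasing_to_zero(self, dialect):
        vals = [density_factor(t, 50, dialect) for t in range(1, 51)]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(0.0, abs=1e-12)

    def test_density_factor_dialects_differ(self):
        # near T=0 the paper dialect tends to exp(-1), the canonical to e
        assert density_factor(1, 10**6, "paper") == pytest.approx(
            math.exp(-1), rel=1e-4)
        assert density_factor(1, 10**6, "canonical") == pytest.approx(
            math.e, rel=1e-4)

    def test_zero_max_iter_rejected(self):
        with pytest.raises(ValueError):
            transfer_operator(1, 0)


class TestComponentUpdates:
    def test_density_volume_forced_r(self):
        obj = _obj([0], [0.2], [0.4], [0])
        best = _obj([0], [0.8], [0.6], [0])
        out = update_density_volume(obj, best, r=0.5)
        assert out.density[0] == pytest.approx(0.5)
        assert out.volume[0] == pytest.approx(0.5)
        # fixed points of the pull
        assert update_density_volume(obj, best, r=0.0).density[0] == 0.2
        assert update_density_volume(obj, best, r=1.0).density[0] == 0.8
        # position untouched
        assert np.array_equal(out.position, obj.position)

    def test_acceleration_hand_values(self):
        ref = _obj([0], [1.0], [1.0], [1.0])
        obj = _obj([0], [1.0], [1.0], [0.0])
        assert compute_acceleration(obj, ref)[0] == pytest.approx(2.0)
        ref2 = _obj([0], [0.5], [0.5], [2.0])
        obj2 = _obj([0], [0.5], [0.8], [0.0])
        assert compute_acceleration(obj2, ref2)[0] == pytest.approx(3.75)

    def test_acceleration_epsilon_floor(self):
        ref = _obj([0], [1.0], [1.0], [1.0])
        obj = _obj([0], [0.0], [0.0], [0.0])
        assert np.isfinite(compute_acceleration(obj, ref)).all()

    def test_normalize_bounds_and_ties(self):
        accels = np.array([[1.0], [3.0], [2.0]])
        out = normalize_acceleration(accels)
        assert out[0, 0] == pytest.approx(0.1)   # population minimum -> lam
        assert out[1, 0] == pytest.approx(1.0)   # maximum -> lam + chi
        tied = normalize_acceleration(np.full((4, 2), 7.0))
        assert np.allclose(tied, 0.55)           # tie rule: lam + chi/2

    def test_normalize_output_in_band(self, rng):
        accels = rng.normal(size=(30, 4)) * 100
        out = normalize_acceleration(accels, chi=0.9, lam=0.1)
        assert out.min() >= 0.1 - 1e-12 and out.max() <= 1.0 + 1e-12

    def test_select_flag_rule(self):
        assert select_flag(k4=0.5, r=0.5) == 1    # I = 0.5, boundary inclusive
        assert select_flag(k4=0.5, r=0.9) == -1   # I = 1.3
        assert select_flag(k4=0.5, r=0.0) == 1    # I = -K4

    def test_moves_hand_values_and_clipping(self):
        lo, hi = np.array([0.0]), np.array([10.0])
        z = exploration_move(np.array([1.0]), np.array([3.0]), 0.5, 0.5,
                             0.5, 2.0, lo, hi)
        assert z[0] == pytest.approx(1.5)
        # d = 0 annihilates the step
        z0 = exploration_move(np.array([1.0]), np.array([9.0]), 0.7, 0.5,
                              0.0, 2.0, lo, hi)
        assert z0[0] == pytest.approx(1.0)
        zb = exploitation_move(np.array([1.0]), np.array([4.0]), np.array([4.0]),
                               0.5, 0.5, 0.0, 0.9, 1, 6.0, 2.0, lo, hi)
        assert zb[0] == pytest.approx(4.0)
        # clipping contract
        zc = exploration_move(np.array([9.0]), np.array([100.0]), 1.0, 1.0,
                              1.0, 2.0, lo, hi)
        assert zc[0] == 10.0


class TestInitialization:
    def test_degenerate_box(self):
        cfg = AOAConfig(dim=2, lower=[5, 5], upper=[5, 5], pop_size=4,
                        max_iter=1, seed=0)
        state = initialize_population(cfg, lambda z: float(z.sum()))
        assert np.all(state.Z == 5.0)

    def test_seeded_determinism(self):
        cfg = AOAConfig(dim=3, lower=[0] * 3, upper=[2] * 3, pop_size=50,
                        max_iter=1, seed=7)
        s1 = initialize_population(cfg, lambda z: float(z.sum()))
        s2 = initialize_population(cfg, lambda z: float(z.sum()))
        assert np.array_equal(s1.Z, s2.Z)
        assert np.array_equal(s1.den, s2.den)

    def test_nonfinite_objective_rejected(self):
        cfg = AOAConfig(dim=1, lower=[0], upper=[1], pop_size=3, max_iter=1)
        with pytest.raises(ValueError, match="non-finite"):
            initialize_population(cfg, lambda z: float("inf"))

    def test_best_is_copy_not_alias(self):
        cfg = AOAConfig(dim=2, lower=[0, 0], upper=[1, 1], pop_size=5,
                        max_iter=1, seed=3)
        state = initialize_population(cfg, lambda z: float(z.sum()))
        state.Z[:] = 99.0
        assert state.best.position.max() <= 1.0


class TestOptimize:
    @pytest.mark.parametrize("dialect", ["paper", "canonical"])
    def test_history_monotone_and_boxed(self, dialect):
        rng = np.random.default_rng(0)
        w = rng.normal(size=3)

        def bumpy(z):
            return float(np.sin(5 * z @ w) + 0.1 * z @ z)

        cfg = AOAConfig(dim=3, lower=[-2] * 3, upper=[2] * 3, pop_size=12,
                        max_iter=40, dialect=dialect, seed=5)
        state = initialize_population(cfg, bumpy)
        prev = state.best.fitness
        for _ in range(cfg.max_iter):
            step(state, bumpy, cfg)
            assert state.best.fitness <= prev + 1e-15
            assert np.all(state.Z >= cfg.lower) and np.all(state.Z <= cfg.upper)
            prev = state.best.fitness

    def test_constant_objective(self):
        cfg = AOAConfig(dim=2, lower=[0, 0], upper=[1, 1], pop_size=5,
                        max_iter=10, seed=1)
        res = optimize(lambda z: 4.2, cfg)
        assert res.best_fitness == 4.2
        assert np.all(res.history == 4.2)

    def test_bitwise_reproducibility(self):
        cfg = AOAConfig(dim=2, lower=[-1, -1], upper=[1, 1], pop_size=8,
                        max_iter=25, seed=9)
        f = lambda z: float(z @ z)
        r1, r2 = optimize(f, cfg), optimize(f, cfg)
        assert np.array_equal(r1.best_position, r2.best_position)
        assert np.array_equal(r1.history, r2.history)

    def test_single_iteration_history(self):
        cfg = AOAConfig(dim=1, lower=[0], upper=[1], pop_size=4, max_iter=1)
        assert optimize(lambda z: float(z[0]), cfg).history.shape == (1,)

    def test_nan_objective_keeps_position(self):
        calls = {"n": 0}

        def flaky(z):
            calls["n"] += 1
            return float("nan") if calls["n"] > 6 else float(z @ z)

        cfg = AOAConfig(dim=2, lower=[0, 0], upper=[1, 1], pop_size=6,
                        max_iter=3, seed=2)
        res = optimize(flaky, cfg)
        assert np.isfinite(res.best_fitness)

    def test_beats_random_search(self):
        """Canonical dialect outperforms pure random search at equal
        evaluation budget on the 2-dim sphere in >= 90% of paired runs."""
        wins = 0
        for seed in range(20):
            cfg = AOAConfig(dim=2, lower=[-5, -5], upper=[5, 5], pop_size=10,
                            max_iter=50, seed=seed)
            res = optimize(lambda z: float(z @ z), cfg)
            rng = np.random.default_rng(seed + 1000)
            budget = cfg.pop_size * (cfg.max_iter + 1)
            draws = -5 + 10 * rng.random((budget, 2))
            assert res.best_fitness is not None
            wins += res.best_fitness < np.min(np.sum(draws**2, axis=1))
        assert wins >= 18
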