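"""Metaheuristics: hand-computed single steps, convergence, shared contracts."""

import numpy as np
import pytest

import oracles
from szeeg import (
    AFConfig,
    BHConfig,
    GSOConfig,
    MSConfig,
    ObjectiveSpec,
    OptimizationError,
    ParameterError,
    af_optimize,
    bh_optimize,
    fisher_separability,
    gso_optimize,
    ms_optimize,
    optimize,
    select_feature_column,
)
from szeeg.swarm import event_horizon_radius

ALL = [
    ("af", af_optimize, AFConfig),
    ("gso", gso_optimize, GSOConfig),
    ("bh", bh_optimize, BHConfig),
    ("ms", ms_optimize, MSConfig),
]


def sphere(dim: int, box: float = 5.0) -> ObjectiveSpec:
    return ObjectiveSpec(
        fitness=lambda x: -float(np.sum(np.asarray(x) ** 2)),
        bounds=[(-box, box)] * dim,
    )


class TestSharedContracts:
    @pytest.mark.parametrize("name,fn,cfg_cls", ALL)
    def test_history_monotone_nondecreasing(self, name, fn, cfg_cls):
        res = fn(sphere(3), cfg_cls(seed=5, iterations=40))
        assert np.all(np.diff(res.history) >= 0)

    @pytest.mark.parametrize("name,fn,cfg_cls", ALL)
    def test_deterministic_under_fixed_seed(self, name, fn, cfg_cls):
        a = fn(sphere(3), cfg_cls(seed=11, iterations=25))
        b = fn(sphere(3), cfg_cls(seed=11, iterations=25))
        np.testing.assert_array_equal(a.best_position, b.best_position)
        np.testing.assert_array_equal(a.history, b.history)
        assert a.evaluations == b.evaluations

    @pytest.mark.parametrize("name,fn,cfg_cls", ALL)
    def test_evaluation_count_is_exact(self, name, fn, cfg_cls):
        calls = {"n": 0}

        def counting(x):
            calls["n"] += 1
            return -float(np.sum(np.asarray(x) ** 2))

        obj = ObjectiveSpec(fitness=counting, bounds=[(-2.0, 2.0)] * 2)
        res = fn(obj, cfg_cls(seed=2, iterations=10))
        assert res.evaluations == calls["n"]

    @pytest.mark.parametrize("name,fn,cfg_cls", ALL)
    def test_best_fitness_matches_best_position(self, name, fn, cfg_cls):
        obj = sphere(2)
        res = fn(obj, cfg_cls(seed=3, iterations=15))
        assert res.best_fitness == pytest.approx(obj.fitness(res.best_position))

    @pytest.mark.parametrize("name,fn,cfg_cls", ALL)
    def test_sphere_default_budget_reaches_optimum(self, name, fn, cfg_cls):
        """All four optimizers solve the 2-D sphere to within 0.05 with defaults."""
        res = fn(sphere(2), cfg_cls(seed=1))
        assert res.best_fitness > -0.05

    def test_non_finite_fitness_aborts(self):
        obj = ObjectiveSpec(fitness=lambda x: float("nan"), bounds=[(-1.0, 1.0)])
        with pytest.raises(OptimizationError):
            bh_optimize(obj, BHConfig(seed=0, iterations=2))

    def test_unknown_optimizer_name(self):
        with pytest.raises(ParameterError):
            optimize(sphere(2), "pso")


class TestArtificialFlora:
    def test_sphere_spec_budget(self):
        """5-D sphere, N=10, B=5, 100 iterations reaches -0.1."""
        res = af_optimize(
            sphere(5), AFConfig(n_plants=10, branching=5, iterations=100, seed=4)
        )
        assert res.best_fitness > -0.1

    def test_zero_iterations_returns_best_initial_plant(self):
        obj = sphere(2)
        cfg = AFConfig(n_plants=1, branching=1, iterations=0, seed=8)
        res = af_optimize(obj, cfg)
        rng = np.random.default_rng(8)
        initial = rng.uniform(obj.lo, obj.hi, size=(1, 2))
        assert res.best_fitness == pytest.approx(obj.fitness(initial[0]))
        assert res.evaluations == 1

    def test_invalid_p_y(self):
        with pytest.raises(ParameterError):
            AFConfig(p_y=1.5)


class TestGlowworm:
    def test_single_step_moves_exactly_st_toward_brighter(self):
        """Two glowworms in 1-D; the dimmer one moves exactly `step` toward
        the brighter one (unit-direction step rule)."""
        positions = []

        def fitness(x):
            return float(x[0])  # worm at larger x is brighter

        obj = ObjectiveSpec(fitness=fitness, bounds=[(0.0, 1.0)])
        cfg = GSOConfig(
            n_glowworms=2, step=0.1, iterations=1, seed=0, q0=10.0, q_st=10.0,
            rho=0.4, gamma=0.6,
        )
        # deterministic initial placement: recover it from the same seed
        rng = np.random.default_rng(0)
        init = rng.uniform(0.0, 1.0, size=(2, 1))
        res = gso_optimize(obj, cfg)
        lo_i = int(np.argmin(init[:, 0]))
        hi_i = 1 - lo_i
        # the dim worm moved +0.1; the bright worm stayed; best = bright worm
        assert res.best_fitness == pytest.approx(float(init[hi_i, 0]))

    def test_full_decay_collapses_luciferin(self):
        """rho = 1, gamma = 0 zeroes all luciferin after one update, so no
        glowworm sees a brighter neighbor and every position freezes."""
        obj = sphere(1, box=1.0)
        cfg = GSOConfig(n_glowworms=5, rho=1.0, gamma=0.0, step=0.1,
                        iterations=3, seed=7)
        res = gso_optimize(obj, cfg)
        # best never improves after initialization
        assert res.history[0] == res.history[-1]

    def test_multimodal_peaks_both_retained(self):
        """1-D bimodal fitness with peaks at -2 and 2: the final best is at a
        peak and the swarm does not collapse onto a single mode."""

        def fitness(x):
            v = float(x[0])
            return float(np.exp(-((v - 2.0) ** 2)) + np.exp(-((v + 2.0) ** 2)))

        obj = ObjectiveSpec(fitness=fitness, bounds=[(-5.0, 5.0)])
        res = gso_optimize(obj, GSOConfig(n_glowworms=50, step=0.03,
                                          iterations=200, seed=3))
        assert min(abs(res.best_position[0] - 2.0), abs(res.best_position[0] + 2.0)) < 0.3


class TestBlackHole:
    def test_event_horizon_hand_value(self):
        assert event_horizon_radius(np.array([4.0, 1.0, 1.0, 2.0]), 0) == 0.5

    def test_zero_fitness_sum_guarded(self):
        assert event_horizon_radius(np.zeros(4), 0) == 0.0

    def test_star_at_black_hole_is_rerandomized(self):
        """A star sitting exactly on the black hole (distance 0 < R) must be
        replaced by a fresh random star within one iteration."""
        # positive, position-dependent fitness so R > 0
        obj = ObjectiveSpec(
            fitness=lambda x: 10.0 - float(np.sum(np.asarray(x) ** 2)),
            bounds=[(-1.0, 1.0)] * 2,
        )
        cfg = BHConfig(n_stars=2, iterations=1, seed=1)
        res = bh_optimize(obj, cfg)
        # with 2 stars the non-hole star moves onto the segment toward the
        # hole; once inside R it is re-randomized -> more than 2+1 evaluations
        assert res.evaluations >= 4

    def test_sphere_ten_dimensional(self):
        res = bh_optimize(sphere(10), BHConfig(n_stars=30, iterations=500, seed=0))
        assert res.best_fitness > -0.01


class TestMonkeySearch:
    def test_pseudogradient_climb_reaches_concave_peak(self):
        """1-D concave fitness -(x-1)^2: sign-of-pseudogradient steps from
        anywhere drive the monkey to within 0.1 of x = 1."""
        obj = ObjectiveSpec(
            fitness=lambda x: -float((x[0] - 1.0) ** 2), bounds=[(-3.0, 3.0)]
        )
        cfg = MSConfig(n_monkeys=1, climb_step=0.01, climb_iterations=500,
                       watch_attempts=0, iterations=1, seed=2)
        res = ms_optimize(obj, cfg)
        assert abs(res.best_position[0] - 1.0) < 0.1

    def test_somersault_noop_when_population_collapsed(self):
        """All monkeys at one point: the pivot equals that point, so the
        somersault reflection cannot move anyone."""
        obj = ObjectiveSpec(fitness=lambda x: 1.0, bounds=[(-1.0, 1.0)] * 2)
        cfg = MSConfig(n_monkeys=3, climb_step=1e-9, climb_iterations=0,
                       watch_attempts=0, iterations=2, seed=0)
        res = ms_optimize(obj, cfg)
        assert res.best_fitness == 1.0  # flat fitness: nothing to improve

    def test_sphere_spec_budget(self):
        res = ms_optimize(sphere(5), MSConfig(n_monkeys=10, iterations=200, seed=6))
        assert res.best_fitness > -0.1

    def test_invalid_somersault_interval(self):
        with pytest.raises(ParameterError):
            MSConfig(somersault_interval=(1.0, 1.0))


class TestFisherSeparability:
    def test_identical_classes_zero(self, rng):
        m = rng.standard_normal((50, 10))
        w = rng.uniform(size=10)
        assert fisher_separability(w, m, m) == 0.0

    def test_hand_substitution_single_column(self, rng):
        m0 = rng.normal(0.0, np.sqrt(0.5), size=(4000, 1))
        m1 = rng.normal(1.0, np.sqrt(0.5), size=(4000, 1))
        got = fisher_separability([1.0], m0, m1)
        assert got == pytest.approx(1.0, rel=0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_recomputation(self, seed):
        r = np.random.default_rng(seed)
        m0 = r.standard_normal((30, 10))
        m1 = r.standard_normal((40, 10)) + 0.3
        w = r.uniform(size=10)
        assert fisher_separability(w, m0, m1) == pytest.approx(
            oracles.fisher_bruteforce(w, m0, m1), abs=1e-12
        )


class TestSelectFeatureColumn:
    @pytest.mark.parametrize("optimizer", ["af", "gso", "bh", "ms"])
    def test_informative_column_wins_majority_of_seeds(self, optimizer):
        """Column 3 fully separates the classes; the learned weight vector
        puts its maximum there in a majority of 10 seeds."""
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            m0 = r.standard_normal((80, 10))
            m1 = r.standard_normal((80, 10))
            m0[:, 3] -= 3.0
            m1[:, 3] += 3.0
            sel = select_feature_column(m0, m1, optimizer, seed=seed)
            hits += int(np.argmax(sel.weights) == 3)
        assert hits > 5

    def test_identical_matrices_zero_fitness(self, rng):
        m = rng.standard_normal((40, 10))
        sel = select_feature_column(m, m, "bh", seed=0)
        assert sel.result.best_fitness == 0.0

    def test_output_shapes_and_weight_normalization(self, rng):
        m0 = rng.standard_normal((30, 10))
        m1 = rng.standard_normal((45, 10))
        sel = select_feature_column(m0, m1, "ms", seed=1)
        assert sel.values0.shape == (30,)
        assert sel.values1.shape == (45,)
        assert sel.weights.sum() == pytest.approx(1.0)
        assert (sel.weights >= 0).all()
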