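import numpy as np
import pytest

from clonalfit import FitnessSpec, OptimizerConfig, fit_csa_de_lr
from clonalfit.exceptions import ConfigurationError, InvalidInputError
from clonalfit.hybrid import (
    clone,
    create_antibodies,
    de_local_search,
    find_best,
    receptor_edit,
    round_half_away,
    select,
)
from clonalfit.metrics import EvalCounter, fitness


class TestRounding:
    @pytest.mark.parametrize("x,expected", [
        (0.5, 1), (1.5, 2), (2.0, 2), (2.4, 2), (2.5, 3), (0.0, 0), (-0.5, -1),
    ])
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected


class TestCreateAntibodies:
    def test_shape_and_bounds(self, rng):
        W = create_antibodies(5, 3, -2.0, 4.0, rng)
        assert W.shape == (5, 3)
        assert np.all(W >= -2.0) and np.all(W < 4.0)

    def test_affine_map_of_uniform(self):
        # same seed: entries must equal lb + u * (ub - lb) for the raw draws
        u = np.random.default_rng(0).random((4, 2))
        W = create_antibodies(4, 2, -1.0, 3.0, np.random.default_rng(0))
        assert np.allclose(W, -1.0 + u * 4.0, atol=1e-15)

    def test_invalid_bounds(self, rng):
        with pytest.raises(ConfigurationError):
            create_antibodies(3, 2, 1.0, 1.0, rng)


class TestClone:
    def test_count(self):
        W = np.arange(8.0).reshape(4, 2)
        C = clone(W, 3)
        assert C.shape == (12, 2)

    def test_alpha_one_is_identity(self):
        W = np.arange(6.0).reshape(3, 2)
        assert np.array_equal(clone(W, 1), W)

    def test_ownership_index(self):
        W = np.arange(8.0).reshape(4, 2)
        C = clone(W, 3)
        assert np.array_equal(C[5], W[5 // 3])
        for k in range(12):
            assert np.array_equal(C[k], W[k // 3])


class TestDeLocalSearch:
    def test_identical_clones_unchanged(self, rng):
        W = np.full((4, 3), 2.5)
        C = clone(W, 2)
        out = de_local_search(C.copy(), 4, 2, 0.7, 1.0, -10, 10, rng)
        assert np.allclose(out, C)

    def test_zero_crossover_rate_unchanged(self, rng):
        C = clone(np.arange(12.0).reshape(4, 3), 2)
        # u <= 0 has probability 2^-53 per coordinate; treat as impossible
        out = de_local_search(C.copy(), 4, 2, 0.7, 0.0, -100, 100, rng)
        assert np.allclose(out, C)

    def test_full_crossover_first_row_is_a_de_trial(self, rng):
        # the clone matrix is mutated in place and sequentially, so only the
        # first clone is guaranteed to draw donors from the original rows;
        # with cr=1 every coordinate is replaced, so that row must be one of
        # the enumerable donor combinations r0 + sf*(r2 - r1), clipped
        W = np.array([[1.0, 1.0], [3.0, 3.0], [5.0, 5.0], [9.0, 9.0]])
        sf, lb, ub = 0.5, -100.0, 100.0
        for trial_seed in range(20):
            out = de_local_search(clone(W, 1), 4, 1, sf, 1.0, lb, ub,
                                  np.random.default_rng(trial_seed))
            others = [W[1], W[2], W[3]]
            candidates = [np.clip(a + sf * (c - b), lb, ub)
                          for a in others for b in others for c in others]
            assert any(np.allclose(out[0], cand, atol=1e-12) for cand in candidates)

    def test_trial_vector_arithmetic(self):
        # donors [1,1],[3,3],[5,5] with sf=0.5 -> 1 + 0.5*(5-3) = 2 per coord
        trial = np.array([1.0, 1.0]) + 0.5 * (np.array([5.0, 5.0]) - np.array([3.0, 3.0]))
        assert np.allclose(trial, [2.0, 2.0])

    def test_mutated_coordinates_clipped(self, rng):
        W = np.array([[1.0], [9.9], [-9.9], [5.0]]) * np.ones((1, 2))
        C = clone(W, 1)
        out = de_local_search(C.copy(), 4, 1, 2.0, 1.0, -10, 10, rng)
        assert np.all(out >= -10) and np.all(out <= 10)

    def test_small_population_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            de_local_search(np.zeros((3, 2)), 3, 1, 0.5, 0.5, -1, 1, rng)


class TestSelect:
    def test_hand_case(self):
        W = np.zeros((2, 2))
        fit = np.array([0.5, 0.9])
        C = np.arange(8.0).reshape(4, 2)
        cfit = np.array([0.6, 0.4, 0.8, 0.95])
        select(W, fit, C, cfit, alpha=2)
        assert np.allclose(fit, [0.6, 0.95])
        assert np.array_equal(W[0], C[0]) and np.array_equal(W[1], C[3])

    def test_no_improvement_keeps_population(self):
        W = np.ones((2, 2))
        fit = np.array([0.9, 0.9])
        C = np.zeros((4, 2))
        cfit = np.array([0.1, 0.2, 0.3, 0.4])
        select(W, fit, C, cfit, alpha=2)
        assert np.allclose(W, 1.0) and np.allclose(fit, 0.9)

    def test_tie_keeps_parent(self):
        W = np.ones((1, 2))
        fit = np.array([0.7])
        C = np.zeros((2, 2))
        cfit = np.array([0.7, 0.7])
        select(W, fit, C, cfit, alpha=2)
        assert np.allclose(W, 1.0)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            P = int(rng.integers(1, 6))
            alpha = int(rng.integers(1, 5))
            D = int(rng.integers(2, 7))
            W = rng.normal(size=(P, D))
            fit = rng.random(P)
            C = rng.normal(size=(P * alpha, D))
            cfit = rng.random(P * alpha)
            W2, fit2 = W.copy(), fit.copy()
            select(W2, fit2, C, cfit, alpha)
            for i in range(P):
                clones = cfit[i * alpha:(i + 1) * alpha]
                best = int(np.argmax(clones))
                if clones[best] > fit[i]:
                    assert fit2[i] == clones[best]
                    assert np.array_equal(W2[i], C[i * alpha + best])
                else:
                    assert fit2[i] == fit[i]
                    assert np.array_equal(W2[i], W[i])

    def test_shape_mismatch(self):
        with pytest.raises(InvalidInputError):
            select(np.zeros((2, 2)), np.zeros(2), np.zeros((3, 2)), np.zeros(3), alpha=2)


class TestReceptorEdit:
    def _fitness_fn(self, counter):
        def fn(params):
            counter.add(params.shape[0])
            return params.sum(axis=1)
        return fn

    def test_replacement_count(self, rng):
        counter = EvalCounter()
        W = np.zeros((10, 3))
        fit = np.linspace(0, 1, 10)
        receptor_edit(W, fit, 0.2, -1, 1, rng, self._fitness_fn(counter))
        assert counter.count == 2
        assert np.count_nonzero((W != 0).any(axis=1)) == 2

    def test_zero_rate_no_change(self, rng):
        counter = EvalCounter()
        W = np.ones((5, 2))
        fit = np.arange(5.0)
        receptor_edit(W, fit, 0.0, -1, 1, rng, self._fitness_fn(counter))
        assert counter.count == 0
        assert np.allclose(W, 1.0)

    def test_best_survives(self, rng):
        counter = EvalCounter()
        W = np.arange(20.0).reshape(10, 2)
        fit = np.linspace(0, 1, 10)
        best_row = W[-1].copy()
        receptor_edit(W, fit, 0.49, -1, 1, rng, self._fitness_fn(counter))
        assert np.array_equal(W[-1], best_row)

    def test_full_replacement_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            receptor_edit(np.zeros((2, 2)), np.zeros(2), 0.9, -1, 1, rng,
                          self._fitness_fn(EvalCounter()))


class TestFindBest:
    def test_first_maximum_on_ties(self):
        gmax, gpar = find_best(np.arange(6.0).reshape(3, 2), np.array([0.2, 0.7, 0.7]))
        assert gmax == 0.7
        assert np.array_equal(gpar, [2.0, 3.0])

    def test_single_antibody(self):
        gmax, gpar = find_best(np.array([[1.0, 2.0]]), np.array([0.3]))
        assert gmax == 0.3 and np.array_equal(gpar, [1.0, 2.0])

    def test_copy_semantics(self):
        W = np.ones((2, 2))
        _, gpar = find_best(W, np.array([0.1, 0.9]))
        gpar[:] = 99.0
        assert np.allclose(W, 1.0)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            find_best(np.empty((0, 2)), np.empty(0))


class TestFitCsaDeLr:
    def test_zero_budget_returns_initial_best(self, separable_dataset, small_config):
        import dataclasses
        cfg = dataclasses.replace(small_config, max_evaluations=0)
        model = fit_csa_de_lr(separable_dataset.X, separable_dataset.y, cfg)
        assert model.evaluations_used == 0
        assert model.best_trace.size == 0
        # must equal the best of the seeded initial population
        rng = np.random.default_rng(cfg.seed)
        W = create_antibodies(cfg.population, 3, cfg.lb, cfg.ub, rng)
        fit_v = fitness(FitnessSpec("f1"), W, separable_dataset.X, separable_dataset.y)
        gmax, gpar = find_best(W, fit_v)
        assert model.fitness == gmax
        assert np.array_equal(model.params, gpar)

    def test_frozen_population_composition(self, rng, separable_dataset):
        # identical antibodies: DE differences are zero and selection is
        # strict, so one full round leaves the population unchanged
        X, y = separable_dataset.X, separable_dataset.y
        W = np.full((4, 3), 1.5)
        fit_v = fitness(FitnessSpec("f1"), W, X, y)
        C = clone(W, 3)
        de_local_search(C, 4, 3, 0.8, 1.0, -10, 10, rng)
        cfit = fitness(FitnessSpec("f1"), C, X, y)
        select(W, fit_v, C, cfit, alpha=3)
        assert np.allclose(W, 1.5)

    def test_determinism(self, separable_dataset, small_config):
        a = fit_csa_de_lr(separable_dataset.X, separable_dataset.y, small_config)
        b = fit_csa_de_lr(separable_dataset.X, separable_dataset.y, small_config)
        assert np.array_equal(a.params, b.params)
        assert np.array_equal(a.best_trace, b.best_trace)
        assert a.fitness == b.fitness and a.evaluations_used == b.evaluations_used

    def test_budget_accounting_and_stop_rule(self, separable_dataset, small_config):
        model = fit_csa_de_lr(separable_dataset.X, separable_dataset.y, small_config)
        cfg = small_config
        per_iter = cfg.population * cfg.clones + round_half_away(
            cfg.population * cfg.editing_rate)
        iters = model.best_trace.size
        assert model.evaluations_used == iters * per_iter
        assert model.evaluations_used >= cfg.max_evaluations
        assert (iters - 1) * per_iter < cfg.max_evaluations

    def test_monotone_trace_and_bounds(self, separable_dataset, small_config):
        seen = []
        model = fit_csa_de_lr(separable_dataset.X, separable_dataset.y, small_config,
                              on_iteration=lambda W, f: seen.append(W.copy()))
        assert np.all(np.diff(model.best_trace) >= 0)
        for W in seen:
            assert np.all(W >= small_config.lb) and np.all(W <= small_config.ub)
        assert np.all(model.params >= small_config.lb)
        assert np.all(model.params <= small_config.ub)

    def test_single_class_rejected(self, small_config):
        X = np.random.default_rng(0).random((10, 2))
        with pytest.raises(InvalidInputError):
            fit_csa_de_lr(X, np.ones(10, dtype=int), small_config)

    def test_invalid_config_rejected(self, separable_dataset):
        cfg = OptimizerConfig(lb=1.0, ub=-1.0)
        with pytest.raises(ConfigurationError):
            fit_csa_de_lr(separable_dataset.X, separable_dataset.y, cfg)
        with pytest.raises(ConfigurationError):
            fit_csa_de_lr(separable_dataset.X, separable_dataset.y,
                          OptimizerConfig(population=3))
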