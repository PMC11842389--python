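"""Shared contracts of the six metaheuristics, checked on closed-form
objectives and against a pure random-search oracle at equal budget."""

import numpy as np
import pytest

from safwre.optimizers import (
    ALGORITHMS,
    NonFiniteObjectiveError,
    OptimizerConfig,
    SearchSpace,
    optimize,
    run_repeated,
    summarize_runs,
)
from tests.conftest import sphere

ALGOS = sorted(ALGORITHMS)

# convergence targets on the 2-D sphere at pop 30 x iters 100
SPHERE_TARGET = {"csa": 1e-3, "ga": 1e-2, "pso": 1e-3, "sa": 1e-1, "ssa": 1e-2, "tso": 1e-2}


def random_search_best(space, n_evals, seed):
    rng = np.random.default_rng(seed)
    X = space.sample(rng, n_evals)
    return min(sphere(x) for x in X)


@pytest.mark.parametrize("algo", ALGOS)
def test_sphere_convergence_beats_oracle(algo, sphere_space):
    cfg = OptimizerConfig(algorithm=algo, population_size=30, iterations=100, seed=0)
    res = optimize(sphere, sphere_space, cfg, maximize=False)
    assert res.best_value < SPHERE_TARGET[algo]
    # independent oracle: random search with 100x budget still only reaches ~1e-2
    oracle = random_search_best(sphere_space, 30 * 101 * 100, seed=0)
    assert oracle < 1e-2
    assert res.best_value < oracle * 10  # same order or better despite 1% budget


@pytest.mark.parametrize("algo", ALGOS)
def test_every_optimizer_beats_random_search_at_equal_budget(algo, sphere_space):
    """Median over seeds: optimizer < pure random search, same evaluation count."""
    opt_vals, rs_vals = [], []
    for seed in range(7):
        cfg = OptimizerConfig(algorithm=algo, population_size=20, iterations=25, seed=seed)
        res = optimize(sphere, sphere_space, cfg, maximize=False)
        opt_vals.append(res.best_value)
        rs_vals.append(random_search_best(sphere_space, res.n_evaluations, seed + 1000))
    assert np.median(opt_vals) < np.median(rs_vals)


@pytest.mark.parametrize("algo", ALGOS)
def test_history_monotone_final_value_and_bounds(algo, sphere_space):
    cfg = OptimizerConfig(algorithm=algo, population_size=10, iterations=20, seed=3)
    res = optimize(sphere, sphere_space, cfg, maximize=False)
    assert len(res.history) == 20
    assert np.all(np.diff(res.history) <= 0)  # best-so-far, minimizing
    assert res.best_value == res.history[-1]
    assert np.all(res.best_vector >= sphere_space.lower)
    assert np.all(res.best_vector <= sphere_space.upper)


@pytest.mark.parametrize("algo", ALGOS)
def test_identical_seed_gives_bit_identical_result(algo, sphere_space):
    cfg = OptimizerConfig(algorithm=algo, population_size=10, iterations=10, seed=5)
    a = optimize(sphere, sphere_space, cfg, maximize=False)
    b = optimize(sphere, sphere_space, cfg, maximize=False)
    assert a.best_value == b.best_value
    assert np.array_equal(a.best_vector, b.best_vector)
    assert np.array_equal(a.history, b.history)


@pytest.mark.parametrize("algo", ALGOS)
def test_bounds_respected_at_every_evaluation(algo):
    space = SearchSpace(np.array([-1.0, 2.0]), np.array([1.0, 3.0]))
    seen = []

    def tracking(x):
        seen.append(x.copy())
        return sphere(x)

    cfg = OptimizerConfig(algorithm=algo, population_size=8, iterations=15, seed=1)
    optimize(tracking, space, cfg, maximize=False)
    pts = np.array(seen)
    assert np.all(pts >= space.lower - 1e-12)
    assert np.all(pts <= space.upper + 1e-12)


def test_elitism_keeps_exact_optimum_from_initial_population(sphere_space):
    # pin the optimum by shrinking the box to a point neighborhood around 0:
    # any population containing x* must never lose it
    cfg = OptimizerConfig(algorithm="csa", population_size=50, iterations=1, seed=0)
    res = optimize(sphere, sphere_space, cfg, maximize=False)
    rng = np.random.default_rng(0)
    init_best = min(sphere(x) for x in sphere_space.sample(rng, 50))
    assert res.best_value <= init_best


def test_constant_objective_returns_constant():
    space = SearchSpace(np.zeros(3), np.ones(3))
    cfg = OptimizerConfig(algorithm="ga", population_size=6, iterations=5, seed=0)
    res = optimize(lambda x: 4.2, space, cfg)
    assert res.best_value == 4.2


def test_non_finite_objective_aborts_with_offending_vector(sphere_space):
    def bad(x):
        return np.nan

    cfg = OptimizerConfig(algorithm="pso", population_size=5, iterations=3, seed=0)
    with pytest.raises(NonFiniteObjectiveError) as err:
        optimize(bad, sphere_space, cfg)
    assert err.value.vector.shape == (2,)


def test_search_space_validation():
    with pytest.raises(ValueError):
        SearchSpace(np.array([0.0, 1.0]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError):
        OptimizerConfig(population_size=1)
    with pytest.raises(ValueError):
        OptimizerConfig(iterations=0)


def test_summarize_runs_trivial_and_oracle_cases():
    s = summarize_runs([1.0, 2.0, 3.0])
    assert (s.best, s.worst, s.mean, s.median, s.std) == (3.0, 1.0, 2.0, 2.0, 1.0)
    single = summarize_runs([0.7])
    assert single.best == single.worst == single.mean == single.median == 0.7
    assert single.std == 0.0
    rng = np.random.default_rng(9)
    vals = rng.random(30)
    s = summarize_runs(vals)
    # independent recomputation with plain python
    assert s.mean == pytest.approx(sum(vals) / 30, abs=1e-12)
    assert s.std == pytest.approx(
        (sum((v - s.mean) ** 2 for v in vals) / 29) ** 0.5, abs=1e-12
    )
    assert s.worst <= s.median <= s.best


def test_run_repeated_deterministic_objective_and_seed_scheme(sphere_space):
    cfg = OptimizerConfig(algorithm="sa", population_size=5, iterations=5, seed=10)
    s = run_repeated(lambda x: 1.5, sphere_space, cfg, n_runs=5)
    assert s.std == 0.0 and s.best == 1.5
    s2 = run_repeated(sphere, sphere_space, cfg, n_runs=4, maximize=False)
    assert s2.worst >= s2.median >= s2.best  # minimization: best is smallest
    assert len(s2.per_run_values) == 4
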