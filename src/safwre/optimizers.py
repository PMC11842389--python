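"""Box-constrained population metaheuristics.

Six swarm-intelligence / stochastic optimizers (circle search, genetic
algorithm, particle swarm, simulated annealing, sparrow search, tuna swarm)
share a single interface: maximize a real-valued objective over a
rectangular box.  All of them are elitist (the best-so-far solution is never
lost), clip every candidate to the box, and are fully reproducible from an
integer seed.

The native direction is maximization (the downstream objective is a
cross-validated ROC-AUC); pass ``maximize=False`` to minimize, in which case
the reported values and history are on the caller's (minimization) scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "SearchSpace",
    "OptimizerConfig",
    "OptimizationResult",
    "RunSummary",
    "ALGORITHMS",
    "optimize",
    "optimize_csa",
    "optimize_ga",
    "optimize_pso",
    "optimize_sa",
    "optimize_ssa",
    "optimize_tso",
    "run_repeated",
    "summarize_runs",
]

Objective = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class SearchSpace:
    """A rectangular (box) search domain."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.ndim != 1 or lo.shape != hi.shape:
            raise ValueError("lower and upper must be 1-D vectors of equal length")
        if not np.all(lo < hi):
            raise ValueError("every lower bound must be strictly below its upper bound")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def n_dims(self) -> int:
        return self.lower.shape[0]

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.lower + rng.random((n, self.n_dims)) * self.width

    @classmethod
    def unit_box(cls, n_dims: int) -> "SearchSpace":
        return cls(np.zeros(n_dims), np.ones(n_dims))


@dataclass
class OptimizerConfig:
    algorithm: str = "csa"
    population_size: int = 50
    iterations: int = 50
    seed: int = 0
    algo_params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.algorithm = self.algorithm.lower()
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    def param(self, name: str, default: float) -> float:
        return float(self.algo_params.get(name, default))


@dataclass
class OptimizationResult:
    best_vector: np.ndarray
    best_value: float
    history: np.ndarray  # best-so-far objective per iteration
    n_evaluations: int


@dataclass
class RunSummary:
    best: float
    worst: float
    mean: float
    median: float
    std: float
    per_run_values: np.ndarray


class NonFiniteObjectiveError(RuntimeError):
    """Raised when the objective returns NaN or +/-inf."""

    def __init__(self, vector: np.ndarray, value: float):
        self.vector = np.asarray(vector)
        self.value = value
        super().__init__(
            f"objective returned non-finite value {value!r} at {self.vector.tolist()}"
        )


class _Evaluator:
    """Wraps the raw objective: sign handling, finiteness check, eval count."""

    def __init__(self, objective: Objective, maximize: bool):
        self._objective = objective
        self._sign = 1.0 if maximize else -1.0
        self.n_evaluations = 0

    def __call__(self, x: np.ndarray) -> float:
        value = float(self._objective(np.asarray(x, dtype=float)))
        self.n_evaluations += 1
        if not math.isfinite(value):
            raise NonFiniteObjectiveError(x, value)
        return self._sign * value

    def batch(self, X: np.ndarray) -> np.ndarray:
        return np.array([self(x) for x in X])


def _finalize(
    evaluator: _Evaluator,
    maximize: bool,
    best_x: np.ndarray,
    best_f: float,
    history: list[float],
) -> OptimizationResult:
    sign = 1.0 if maximize else -1.0
    return OptimizationResult(
        best_vector=np.array(best_x, dtype=float),
        best_value=sign * best_f,
        history=sign * np.asarray(history, dtype=float),
        n_evaluations=evaluator.n_evaluations,
    )


# ---------------------------------------------------------------------------
# Circle search algorithm
# ---------------------------------------------------------------------------

def optimize_csa(
    objective: Objective,
    space: SearchSpace,
    config: OptimizerConfig,
    maximize: bool = True,
) -> OptimizationResult:
    """Circle search: candidates move along the tangent direction toward the
    incumbent best ("circle center"), X_i <- X* + (X* - X_i) * tan(theta_i).

    The angle schedule shrinks with iteration count and switches from broad
    exploration to fine exploitation after a fraction ``c`` of the budget:
    with w = pi - pi*(t/T)^2 and p = 1 - 0.9*sqrt(t/T), theta is w*U(0,1) in
    the exploitation phase (t > c*T) and w*p before it.
    """
    ev = _Evaluator(objective, maximize)
    rng = np.random.default_rng(config.seed)
    c = config.param("c", 0.8)
    T = config.iterations

    X = space.sample(rng, config.population_size)
    F = ev.batch(X)
    i_best = int(np.argmax(F))
    best_x, best_f = X[i_best].copy(), F[i_best]

    history: list[float] = []
    for t in range(1, T + 1):
        frac = t / T
        w = math.pi - math.pi * frac**2
        p = 1.0 - 0.9 * math.sqrt(frac)
        if t > c * T:  # exploitation: random shrinking angles
            theta = w * rng.random(config.population_size)
        else:  # exploration: deterministic wide angle
            theta = np.full(config.population_size, w * p)
        X = space.clip(best_x + (best_x - X) * np.tan(theta)[:, None])
        F = ev.batch(X)
        i = int(np.argmax(F))
        if F[i] > best_f:
            best_x, best_f = X[i].copy(), F[i]
        history.append(best_f)
    return _finalize(ev, maximize, best_x, best_f, history)


# ---------------------------------------------------------------------------
# Genetic algorithm (real-coded)
# ---------------------------------------------------------------------------

def optimize_ga(
    objective: Objective,
    space: SearchSpace,
    config: OptimizerConfig,
    maximize: bool = True,
) -> OptimizationResult:
    """Real-coded GA: tournament selection, blend (BLX-alpha) crossover,
    Gaussian mutation, one-elite survival."""
    ev = _Evaluator(objective, maximize)
    rng = np.random.default_rng(config.seed)
    n, d = config.population_size, space.n_dims
    alpha = config.param("blx_alpha", 0.5)
    p_cross = config.param("p_crossover", 0.9)
    p_mut = config.param("p_mutation", 1.0 / d)
    sigma = config.param("mutation_sigma", 0.1) * space.width
    k_tour = int(config.param("tournament_size", 3))

    X = space.sample(rng, n)
    F = ev.batch(X)
    i_best = int(np.argmax(F))
    best_x, best_f = X[i_best].copy(), F[i_best]

    def tournament() -> np.ndarray:
        idx = rng.integers(0, n, size=k_tour)
        return X[idx[np.argmax(F[idx])]]

    history: list[float] = []
    for _ in range(config.iterations):
        children = np.empty_like(X)
        for j in range(0, n, 2):
            p1, p2 = tournament(), tournament()
            if rng.random() < p_cross:
                lo = np.minimum(p1, p2) - alpha * np.abs(p1 - p2)
                hi = np.maximum(p1, p2) + alpha * np.abs(p1 - p2)
                c1 = lo + rng.random(d) * (hi - lo)
                c2 = lo + rng.random(d) * (hi - lo)
            else:
                c1, c2 = p1.copy(), p2.copy()
            children[j] = c1
            if j + 1 < n:
                children[j + 1] = c2
        mutate = rng.random(children.shape) < p_mut
        children = children + mutate * rng.normal(0.0, 1.0, children.shape) * sigma
        children = space.clip(children)
        Fc = ev.batch(children)
        # elitism: worst child replaced by incumbent best
        i_worst = int(np.argmin(Fc))
        children[i_worst], Fc[i_worst] = best_x, best_f
        X, F = children, Fc
        i = int(np.argmax(F))
        if F[i] > best_f:
            best_x, best_f = X[i].copy(), F[i]
        history.append(best_f)
    return _finalize(ev, maximize, best_x, best_f, history)


# ---------------------------------------------------------------------------
# Particle swarm optimization
# ---------------------------------------------------------------------------

def optimize_pso(
    objective: Objective,
    space: SearchSpace,
    config: OptimizerConfig,
    maximize: bool = True,
) -> OptimizationResult:
    """Global-best PSO with linearly decaying inertia (0.9 -> 0.4),
    c1 = c2 = 2, velocities clamped to 20% of the box width."""
    ev = _Evaluator(objective, maximize)
    rng = np.random.default_rng(config.seed)
    n, d = config.population_size, space.n_dims
    w_start = config.param("inertia_start", 0.9)
    w_end = config.param("inertia_end", 0.4)
    c1 = config.param("c1", 2.0)
    c2 = config.param("c2", 2.0)
    v_max = config.param("velocity_clamp", 0.2) * space.width

    X = space.sample(rng, n)
    V = np.zeros((n, d))
    F = ev.batch(X)
    P, Fp = X.copy(), F.copy()  # personal bests
    i_best = int(np.argmax(F))
    best_x, best_f = X[i_best].copy(), F[i_best]

    history: list[float] = []
    T = config.iterations
    for t in range(T):
        w = w_start + (w_end - w_start) * (t / max(T - 1, 1))
        r1, r2 = rng.random((n, d)), rng.random((n, d))
        V = w * V + c1 * r1 * (P - X) + c2 * r2 * (best_x - X)
        V = np.clip(V, -v_max, v_max)
        X = space.clip(X + V)
        F = ev.batch(X)
        improved = F > Fp
        P[improved], Fp[improved] = X[improved], F[improved]
        i = int(np.argmax(Fp))
        if Fp[i] > best_f:
            best_x, best_f = P[i].copy(), Fp[i]
        history.append(best_f)
    return _finalize(ev, maximize, best_x, best_f, history)


# ---------------------------------------------------------------------------
# Simulated annealing (multi-start chains for budget parity)
# ---------------------------------------------------------------------------

def optimize_sa(
    objective: Objective,
    space: SearchSpace,
    config: OptimizerConfig,
    maximize: bool = True,
) -> OptimizationResult:
    """Simulated annealing run as ``population_size`` independent chains so
    the total evaluation budget matches the population algorithms.  Gaussian
    proposals with scale proportional to box width and temperature;
    exponential cooling; Metropolis acceptance."""
    ev = _Evaluator(objective, maximize)
    rng = np.random.default_rng(config.seed)
    n = config.population_size
    t0 = config.param("initial_temperature", 1.0)
    cooling = config.param("cooling", 0.9)
    step = config.param("step_fraction", 0.3) * space.width

    X = space.sample(rng, n)  # current state of each chain
    F = ev.batch(X)
    i_best = int(np.argmax(F))
    best_x, best_f = X[i_best].copy(), F[i_best]

    history: list[float] = []
    temp = t0
    for _ in range(config.iterations):
        proposals = space.clip(
            X + rng.normal(0.0, 1.0, X.shape) * step * max(temp / t0, 1e-12)
        )
        Fp = ev.batch(proposals)
        delta = Fp - F
        accept = (delta >= 0) | (rng.random(n) < np.exp(np.minimum(delta, 0.0) / max(temp, 1e-300)))
        X[accept], F[accept] = proposals[accept], Fp[accept]
        i = int(np.argmax(Fp))
        if Fp[i] > best_f:
            best_x, best_f = proposals[i].copy(), Fp[i]
        history.append(best_f)
        temp *= cooling
    return _finalize(ev, maximize, best_x, best_f, history)


# ---------------------------------------------------------------------------
# Sparrow search algorithm
# ---------------------------------------------------------------------------

def optimize_ssa(
    objective: Objective,
    space: SearchSpace,
    config: OptimizerConfig,
    maximize: bool = True,
) -> OptimizationResult:
    """Sparrow search: the fittest fraction act as producers that lead the
    search, the remainder scrounge around the producers, and a random scout
    fraction jumps when danger is perceived (alarm value above threshold)."""
    ev = _Evaluator(objective, maximize)
    rng = np.random.default_rng(config.seed)
    n, d = config.population_size, space.n_dims
    n_prod = max(1, int(round(config.param("producer_fraction", 0.2) * n)))
    n_scout = max(1, int(round(config.param("scout_fraction", 0.1) * n)))
    alarm = config.param("alarm_threshold", 0.8)
    T = config.iterations

    X = space.sample(rng, n)
    F = ev.batch(X)
    i_best = int(np.argmax(F))
    best_x, best_f = X[i_best].copy(), F[i_best]

    history: list[float] = []
    for t in range(1, T + 1):
        order = np.argsort(-F)  # fittest first
        X, F = X[order], F[order]
        new_X = X.copy()
        r2 = rng.random()
        for rank in range(n_prod):  # producers
            if r2 < alarm:
                new_X[rank] = X[rank] * np.exp(-rank / (rng.random() * T + 1e-12))
            else:
                new_X[rank] = X[rank] + rng.normal(size=d)
        x_best_prod = new_X[0]
        x_worst = X[-1]
        for rank in range(n_prod, n):  # scroungers
            if rank > n / 2:
                new_X[rank] = rng.normal(size=d) * np.exp((x_worst - X[rank]) / (rank + 1) ** 2)
            else:
                A = rng.choice([-1.0, 1.0], size=d)
                new_X[rank] = x_best_prod + np.abs(X[rank] - x_best_prod) * A / d
        scouts = rng.choice(n, size=n_scout, replace=False)
        f_worst = F.min()
        for rank in scouts:  # danger-aware jumps
            if F[rank] < best_f:
                new_X[rank] = best_x + rng.normal(size=d) * np.abs(X[rank] - best_x)
            else:
                k = rng.uniform(-1, 1)
                new_X[rank] = X[rank] + k * np.abs(X[rank] - x_worst) / (best_f - F[rank] + 1e-50)
        X = space.clip(new_X)
        F = ev.batch(X)
        i = int(np.argmax(F))
        if F[i] > best_f:
            best_x, best_f = X[i].copy(), F[i]
        history.append(best_f)
    return _finalize(ev, maximize, best_x, best_f, history)


# ---------------------------------------------------------------------------
# Tuna swarm optimization
# ---------------------------------------------------------------------------

def optimize_tso(
    objective: Objective,
    space: SearchSpace,
    config: OptimizerConfig,
    maximize: bool = True,
) -> OptimizationResult:
    """Tuna swarm: each individual follows either spiral foraging (tight
    spirals around the prey, information shared with the preceding swarm
    member) or parabolic foraging (a parabola anchored at the prey), chosen
    stochastically; a small probability ``z`` re-seeds an individual
    uniformly to preserve exploration."""
    ev = _Evaluator(objective, maximize)
    rng = np.random.default_rng(config.seed)
    n, d = config.population_size, space.n_dims
    a = config.param("a", 0.7)
    b = config.param("spiral_b", 0.05)
    z = config.param("z", 0.05)
    T = config.iterations

    X = space.sample(rng, n)
    F = ev.batch(X)
    i_best = int(np.argmax(F))
    best_x, best_f = X[i_best].copy(), F[i_best]

    history: list[float] = []
    for t in range(1, T + 1):
        frac = t / T
        a1 = a + (1 - a) * frac
        a2 = (1 - a) - (1 - a) * frac
        new_X = np.empty_like(X)
        for i in range(n):
            if rng.random() < z:
                new_X[i] = space.sample(rng, 1)[0]
                continue
            if rng.random() < 0.5:  # spiral foraging
                l = rng.uniform(-1.0, 1.0)
                beta = math.exp(b * l) * math.cos(2 * math.pi * l)
                ref = best_x if rng.random() < frac else space.sample(rng, 1)[0]
                prev = new_X[i - 1] if i > 0 else X[i]
                new_X[i] = a1 * (ref + beta * np.abs(ref - X[i])) + a2 * prev
            else:  # parabolic foraging
                tf = 1.0 if rng.random() < 0.5 else -1.0
                p = (1 - frac) ** frac
                if rng.random() < 0.5:
                    new_X[i] = best_x + rng.random(d) * (best_x - X[i]) + tf * p**2 * (best_x - X[i])
                else:
                    new_X[i] = tf * p**2 * X[i]
        X = space.clip(new_X)
        F = ev.batch(X)
        i = int(np.argmax(F))
        if F[i] > best_f:
            best_x, best_f = X[i].copy(), F[i]
        history.append(best_f)
    return _finalize(ev, maximize, best_x, best_f, history)


ALGORITHMS: dict[str, Callable[..., OptimizationResult]] = {
    "csa": optimize_csa,
    "ga": optimize_ga,
    "pso": optimize_pso,
    "sa": optimize_sa,
    "ssa": optimize_ssa,
    "tso": optimize_tso,
}


def optimize(
    objective: Objective,
    space: SearchSpace,
    config: OptimizerConfig,
    maximize: bool = True,
) -> OptimizationResult:
    """Dispatch on ``config.algorithm``."""
    try:
        fn = ALGORITHMS[config.algorithm]
    except KeyError:
        raise ValueError(
            f"unknown algorithm {config.algorithm!r}; choose from {sorted(ALGORITHMS)}"
        ) from None
    return fn(objective, space, config, maximize=maximize)


def summarize_runs(per_run_values: Sequence[float]) -> RunSummary:
    """Best/Worst/Mean/Median/Std over repeated runs (maximization: best is
    the largest value).  Sample standard deviation (n-1 denominator); zero
    for a single run."""
    values = np.asarray(per_run_values, dtype=float)
    if values.size == 0:
        raise ValueError("per_run_values must be non-empty")
    std = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return RunSummary(
        best=float(values.max()),
        worst=float(values.min()),
        mean=float(values.mean()),
        median=float(np.median(values)),
        std=std,
        per_run_values=values,
    )


def run_repeated(
    objective: Objective,
    space: SearchSpace,
    config: OptimizerConfig,
    n_runs: int,
    maximize: bool = True,
) -> RunSummary:
    """Repeat the optimization ``n_runs`` times; run r uses seed + r.

    A failed run aborts the whole batch with the failing seed reported.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    values = []
    for r in range(n_runs):
        cfg = OptimizerConfig(
            algorithm=config.algorithm,
            population_size=config.population_size,
            iterations=config.iterations,
            seed=config.seed + r,
            algo_params=dict(config.algo_params),
        )
        try:
            result = optimize(objective, space, cfg, maximize=maximize)
        except Exception as exc:
            raise RuntimeError(f"run {r} (seed {cfg.seed}) failed: {exc}") from exc
        values.append(result.best_value)
    summary = summarize_runs(values)
    if not maximize:  # best is the smallest value when minimizing
        summary = RunSummary(
            best=summary.worst,
            worst=summary.best,
            mean=summary.mean,
            median=summary.median,
            std=summary.std,
            per_run_values=summary.per_run_values,
        )
    return summary
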