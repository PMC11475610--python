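"""Equilibrium Optimizer (EO), a population-based bounded maximizer.

EO moves a population of candidate solutions toward members of an
*equilibrium pool* — the four best candidates seen in the current
generation plus their coordinate-wise mean.  Each coordinate of a
candidate relaxes exponentially toward the randomly chosen pool member
while a generation-rate term injects perturbations, balancing
exploitation (search near the current best) against exploration
(jumps into unvisited regions of the box).

The update applied to every candidate ``C`` each iteration is::

    C_new = Ceq + (C - Ceq) * F + G / (lam * V) * (1 - F)

with ``Ceq`` drawn uniformly from the pool, ``lam`` a fresh uniform(0,1)
draw per coordinate, and

    t   = (1 - it/T) ** (a2 * it/T)
    F   = a1 * sign(r - 0.5) * (exp(-lam * t) - 1)
    G   = GCP * (Ceq - lam * C) * F,   GCP = 0.5 * r1  if r2 >= GP else 0

where ``r`` is uniform per coordinate and ``r1, r2`` are uniform scalars
per candidate.  The convention here is maximization; pass the negated
objective to minimize.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "EOConfig",
    "Candidate",
    "EquilibriumPool",
    "EOResult",
    "init_population",
    "build_pool",
    "update_position",
    "optimize",
]

#: floor applied to every lambda draw so the G / (lam * V) term never
#: divides by zero
_LAMBDA_FLOOR = 1e-12


@dataclass(frozen=True)
class EOConfig:
    """Settings for one EO run.

    Parameters
    ----------
    dimension
        Number of coordinates in each candidate position.
    population_size
        Candidates per generation.  Must be at least 5 so the
        equilibrium pool (4 best + mean) is well defined.
    max_iterations
        Number of position-update generations.
    lower_bound, upper_bound
        Box constraints, scalar or one value per dimension.
    V
        Control-volume constant of the update; usually 1 or 2.
    a1, a2
        Exploration and exploitation constants in the exponential term.
    GP
        Generation probability: the chance that the generation-rate
        contribution of a candidate is switched off in an update.
    seed
        Seed for the run's random generator.
    """

    dimension: int
    population_size: int = 30
    max_iterations: int = 1000
    lower_bound: float | Sequence[float] = 0.0
    upper_bound: float | Sequence[float] = 1.0
    V: float = 1.0
    a1: float = 2.0
    a2: float = 1.0
    GP: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be a positive integer")
        if self.population_size < 5:
            raise ValueError(
                "population_size must be at least 5 (equilibrium pool needs "
                "4 distinct best candidates plus their mean)"
            )
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be a positive integer")
        if self.V <= 0:
            raise ValueError("V must be positive")
        lo, hi = self.bounds()
        if not np.all(lo < hi):
            raise ValueError("lower_bound must be strictly below upper_bound")

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Lower and upper bounds broadcast to ``dimension`` vectors."""
        lo = np.broadcast_to(np.asarray(self.lower_bound, float), (self.dimension,))
        hi = np.broadcast_to(np.asarray(self.upper_bound, float), (self.dimension,))
        return lo.copy(), hi.copy()

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("lower_bound", "upper_bound"):
            if not np.isscalar(d[key]):
                d[key] = list(np.asarray(d[key], float))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EOConfig":
        return cls(**d)


@dataclass
class Candidate:
    """One population member: a position in the box and its fitness."""

    position: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class EquilibriumPool:
    """The four fittest candidates plus their coordinate-wise mean."""

    members: list[Candidate] = field(default_factory=list)

    @property
    def ceq_ave(self) -> Candidate:
        return self.members[-1]

    def choose(self, rng: np.random.Generator) -> Candidate:
        """Draw one pool member uniformly at random."""
        return self.members[rng.integers(len(self.members))]


@dataclass
class EOResult:
    """Best solution found and the per-iteration best-so-far trace."""

    best_position: np.ndarray
    best_fitness: float
    fitness_trace: np.ndarray


class FitnessError(RuntimeError):
    """Raised when the objective fails; carries the offending position."""

    def __init__(self, position: np.ndarray, cause: BaseException):
        self.position = np.asarray(position)
        super().__init__(
            f"fitness function raised {cause!r} at position {self.position}"
        )


def init_population(
    config: EOConfig, rng: np.random.Generator | None = None
) -> list[Candidate]:
    """Draw ``population_size`` positions uniformly inside the box.

    Fitness is left unset; callers evaluate it before ranking.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds()
    positions = rng.uniform(lo, hi, size=(config.population_size, config.dimension))
    return [Candidate(position=p) for p in positions]


def build_pool(candidates: Sequence[Candidate]) -> EquilibriumPool:
    """Rank candidates by fitness and assemble the equilibrium pool.

    The pool holds the four fittest candidates (ties broken by lower
    index, so the result is a pure function of the (fitness, index)
    pairs) plus a synthetic candidate at their coordinate-wise mean.
    """
    if len(candidates) < 4:
        raise ValueError("equilibrium pool needs at least 4 evaluated candidates")
    fitness = []
    for c in candidates:
        if c.fitness is None:
            raise ValueError("all candidates must be evaluated before pooling")
        fitness.append(c.fitness)
    # stable argsort on negated fitness -> ties resolved by lower index
    order = np.argsort(-np.asarray(fitness), kind="stable")[:4]
    best = [Candidate(candidates[i].position.copy(), candidates[i].fitness) for i in order]
    mean_pos = np.mean([c.position for c in best], axis=0)
    mean_fit = float(np.mean([c.fitness for c in best]))
    return EquilibriumPool(members=best + [Candidate(mean_pos, mean_fit)])


def update_position(
    c: Candidate,
    ceq: Candidate,
    iteration: int,
    config: EOConfig,
    rng: np.random.Generator,
    *,
    F: np.ndarray | float | None = None,
    G: np.ndarray | float | None = None,
) -> np.ndarray:
    """One exponential-relaxation update of a candidate toward ``ceq``.

    ``F`` and ``G`` may be forced (e.g. in tests) instead of drawn;
    when forced, ``lam`` still participates in the ``G/(lam V)`` term.
    The result is clamped to the box.
    """
    if not 1 <= iteration <= config.max_iterations:
        raise ValueError("iteration must lie in [1, max_iterations]")
    dim = config.dimension
    lam = np.maximum(rng.uniform(size=dim), _LAMBDA_FLOOR)
    pos = np.asarray(c.position, float)
    ceq_pos = np.asarray(ceq.position, float)

    if F is None:
        frac = iteration / config.max_iterations
        t = (1.0 - frac) ** (config.a2 * frac)
        r = rng.uniform(size=dim)
        F = config.a1 * np.sign(r - 0.5) * (np.exp(-lam * t) - 1.0)
    F = np.asarray(F, float)

    if G is None:
        r1, r2 = rng.uniform(size=2)
        gcp = 0.5 * r1 if r2 >= config.GP else 0.0
        G = gcp * (ceq_pos - lam * pos) * F
    G = np.asarray(G, float)

    new = ceq_pos + (pos - ceq_pos) * F + G / (lam * config.V) * (1.0 - F)
    lo, hi = config.bounds()
    return np.clip(new, lo, hi)


def optimize(
    fitness_fn: Callable[[np.ndarray], float],
    config: EOConfig,
    *,
    init_positions: np.ndarray | None = None,
) -> EOResult:
    """Maximize ``fitness_fn`` over the box with EO.

    Each generation every candidate is evaluated, the equilibrium pool
    is rebuilt from the current population, and every candidate moves
    toward a randomly chosen pool member.  The best candidate ever seen
    is tracked separately (elitism), so ``fitness_trace`` is monotone
    non-decreasing and the reported optimum is never lost to a bad move.

    Parameters
    ----------
    fitness_fn
        Objective, larger is better; must be defined on the whole box.
    config
        Run settings including the seed.
    init_positions
        Optional warm-start positions (rows) substituted for the first
        rows of the random initial population, e.g. known feasible
        points whose fitness the optimum must dominate.
    """
    rng = np.random.default_rng(config.seed)
    population = init_population(config, rng)
    if init_positions is not None:
        warm = np.atleast_2d(np.asarray(init_positions, float))
        if warm.shape[1] != config.dimension:
            raise ValueError("warm-start positions have wrong dimension")
        lo, hi = config.bounds()
        for i, row in enumerate(warm[: len(population)]):
            population[i] = Candidate(np.clip(row, lo, hi))

    def evaluate(pos: np.ndarray) -> float:
        try:
            return float(fitness_fn(pos))
        except Exception as exc:  # re-raise with the offending position
            raise FitnessError(pos, exc) from exc

    best_pos: np.ndarray | None = None
    best_fit = -np.inf
    trace = np.empty(config.max_iterations)

    for it in range(1, config.max_iterations + 1):
        for c in population:
            c.fitness = evaluate(c.position)
            if c.fitness > best_fit:
                best_fit = c.fitness
                best_pos = c.position.copy()
        pool = build_pool(population)
        trace[it - 1] = best_fit
        for c in population:
            ceq = pool.choose(rng)
            c.position = update_position(c, ceq, it, config, rng)
            c.fitness = None

    assert best_pos is not None
    return EOResult(best_position=best_pos, best_fitness=best_fit, fitness_trace=trace)
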