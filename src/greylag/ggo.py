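"""Continuous Greylag Goose Optimization (GGO).

A population ("gaggle") of candidate solutions is split into an
exploration group and an exploitation group whose sizes are rebalanced
dynamically: exploitation grows as iterations pass, and a stagnating
leader triggers a shift back toward exploration.  Exploration agents
move toward the leader, combine three random "paddling" agents, or
follow a logarithmic spiral around the leader; exploitation agents are
guided by the three best "sentries" or search locally around a
near-leader "flock" agent.  Elitism keeps the best-ever solution (the
leader) intact across iterations, and a component-wise uniform mutation
maintains diversity.  Minimization convention throughout.

All randomness flows through one seeded :class:`numpy.random.Generator`
per run; draws are consumed in a fixed documented order, so a run is a
pure function of (objective, config).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "GGOConfig",
    "Agent",
    "Population",
    "UpdateDraws",
    "OptimizationResult",
    "z_schedule",
    "r1_schedule",
    "a_schedule",
    "draw_coefficients",
    "explore_leader",
    "explore_paddles",
    "explore_spiral",
    "exploit_sentries",
    "exploit_flock",
    "resize_groups",
    "mutate",
    "run_ggo",
]

EXPLORATION = "exploration"
EXPLOITATION = "exploitation"


# ---------------------------------------------------------------------------
# Configuration and state containers
# ---------------------------------------------------------------------------

@dataclass
class GGOConfig:
    """All constants of a GGO run.

    Parameters
    ----------
    population_size:
        Number of agents ``n`` (>= 4; the paddling update needs three
        distinct partners).
    max_iterations:
        Iteration budget ``t_max`` (>= 1).
    bounds:
        Per-dimension ``(lower, upper)`` pairs defining the search box.
    a_start, a_end:
        Endpoints of the linear schedule of the encircling parameter
        ``a`` (default 2 -> 0).
    spiral_constant:
        Shape constant ``b`` of the logarithmic spiral update.
    schedule_constant:
        Constant ``c`` of the scheduled-``r1`` diagnostic,
        ``r1(t) = c * (1 - t / t_max)``.
    w_low, w_high:
        Bounds of the uniform weights ``w1..w4`` (default [0, 2]).
    stagnation_threshold:
        Consecutive non-improving iterations after which agents are
        shifted back into the exploration group (default 3).
    group_shift_per_iteration:
        How many agents migrate between groups per iteration (default 1).
    min_group_size:
        Floor for both group sizes (default 1).
    mutation_rate:
        Per-component probability of a uniform redraw within bounds
        (default 0.05); the current best agent is never mutated.
    seed:
        Seed of the single random generator driving the run.
    """

    population_size: int = 20
    max_iterations: int = 100
    bounds: Sequence[tuple[float, float]] = ((0.0, 1.0),)
    a_start: float = 2.0
    a_end: float = 0.0
    spiral_constant: float = 1.0
    schedule_constant: float = 2.0
    w_low: float = 0.0
    w_high: float = 2.0
    stagnation_threshold: int = 3
    group_shift_per_iteration: int = 1
    min_group_size: int = 1
    mutation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if self.population_size < 2 * self.min_group_size:
            raise ValueError("population_size must be >= 2 * min_group_size")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.w_low > self.w_high:
            raise ValueError("w_low must not exceed w_high")
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")
        lo, hi = self.lower_bounds, self.upper_bounds
        if np.any(lo >= hi):
            raise ValueError("each dimension needs lower < upper bounds")

    @property
    def dimension(self) -> int:
        return len(self.bounds)

    @property
    def lower_bounds(self) -> np.ndarray:
        return np.asarray([b[0] for b in self.bounds], dtype=float)

    @property
    def upper_bounds(self) -> np.ndarray:
        return np.asarray([b[1] for b in self.bounds], dtype=float)


@dataclass
class Agent:
    """One candidate solution with its objective value and group tag."""

    position: np.ndarray
    fitness: float
    group_tag: str = EXPLORATION


@dataclass
class Population:
    """The gaggle: agents, the archived leader, and group bookkeeping.

    ``n1 + n2 == len(agents)`` always; the leader is an elitist copy of
    the best solution ever evaluated and never worsens.
    """

    agents: list[Agent]
    leader: Agent
    n1: int
    n2: int
    stagnation_counter: int = 0

    @property
    def size(self) -> int:
        return len(self.agents)


@dataclass
class UpdateDraws:
    """Random coefficients consumed by one position update.

    ``r1`` and ``r2`` are drawn per dimension so that ``A = 2a*r1 - a``
    and ``C = 2*r2`` are vectors; ``r3``..``r5``, ``l`` and the weights
    are scalars.  ``z`` and the scheduled quantities are filled in by
    the caller.
    """

    r1: np.ndarray
    r2: np.ndarray
    r3: float
    r4: float
    r5: float
    l: float
    w1: float
    w2: float
    w3: float
    w4: float
    A: np.ndarray
    C: np.ndarray
    a: float
    z: float = 0.0
    r1_sched: float = 0.0


@dataclass
class OptimizationResult:
    """Outcome of a GGO run.

    ``fitness_trace`` holds the best-so-far objective value after each
    iteration (length ``t_max``, non-increasing); ``group_size_trace``
    holds ``(n1, n2)`` per iteration.
    """

    best_position: np.ndarray
    best_fitness: float
    fitness_trace: np.ndarray
    group_size_trace: list[tuple[int, int]]
    evaluations: int
    seed_used: int


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

def z_schedule(t: int, t_max: int) -> float:
    """Quadratically decaying exploration weight, ``1 - (t/t_max)**2``."""
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    if not 0 <= t <= t_max:
        raise ValueError(f"iteration t={t} outside [0, {t_max}]")
    return 1.0 - (t / t_max) ** 2


def r1_schedule(t: int, t_max: int, c: float) -> float:
    """Linearly decaying scheduled coefficient ``c * (1 - t/t_max)``."""
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    if not 0 <= t <= t_max:
        raise ValueError(f"iteration t={t} outside [0, {t_max}]")
    return c * (1.0 - t / t_max)


def a_schedule(t: int, t_max: int, a_start: float = 2.0, a_end: float = 0.0) -> float:
    """Encircling parameter, linear from ``a_start`` to ``a_end``."""
    return a_start + (a_end - a_start) * (t / t_max)


# ---------------------------------------------------------------------------
# Coefficient draws
# ---------------------------------------------------------------------------

def draw_coefficients(
    a: float, rng: np.random.Generator, cfg: GGOConfig, dimension: int | None = None
) -> UpdateDraws:
    """Draw one full set of update coefficients.

    Fixed draw order (for reproducibility): r1 vector, r2 vector, then
    r3, r4, r5, l, w1, w2, w3, w4.  ``A = 2a*r1 - a`` and ``C = 2*r2``
    hold exactly.
    """
    d = cfg.dimension if dimension is None else dimension
    r1 = rng.random(d)
    r2 = rng.random(d)
    r3, r4, r5 = rng.random(3)
    l = rng.uniform(-1.0, 1.0)
    w1, w2, w3, w4 = rng.uniform(cfg.w_low, cfg.w_high, size=4)
    return UpdateDraws(
        r1=r1, r2=r2, r3=float(r3), r4=float(r4), r5=float(r5), l=float(l),
        w1=float(w1), w2=float(w2), w3=float(w3), w4=float(w4),
        A=2.0 * a * r1 - a, C=2.0 * r2, a=a,
    )


def _clip(x: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    return np.clip(x, lower, upper)


# ---------------------------------------------------------------------------
# Exploration updates
# ---------------------------------------------------------------------------

def explore_leader(
    x: np.ndarray,
    leader: np.ndarray,
    draws: UpdateDraws,
    lower: np.ndarray,
    upper: np.ndarray,
) -> np.ndarray:
    """Encircle the leader: ``X* - A * |C*X* - X|``."""
    x = np.asarray(x, dtype=float)
    leader = np.asarray(leader, dtype=float)
    if x.shape != leader.shape:
        raise ValueError("agent and leader positions must share dimension")
    new = leader - draws.A * np.abs(draws.C * leader - x)
    return _clip(new, lower, upper)


def explore_paddles(
    x: np.ndarray,
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    z: float,
    draws: UpdateDraws,
    lower: np.ndarray,
    upper: np.ndarray,
) -> np.ndarray:
    """Blend three random paddling agents:
    ``w1*p1 + z*w2*(p2 - p3) + (1 - z)*w3*(x - p1)``."""
    new = (
        draws.w1 * np.asarray(p1, dtype=float)
        + z * draws.w2 * (np.asarray(p2, dtype=float) - np.asarray(p3, dtype=float))
        + (1.0 - z) * draws.w3 * (np.asarray(x, dtype=float) - np.asarray(p1, dtype=float))
    )
    return _clip(new, lower, upper)


def explore_spiral(
    x: np.ndarray,
    leader: np.ndarray,
    draws: UpdateDraws,
    b: float,
    lower: np.ndarray,
    upper: np.ndarray,
) -> np.ndarray:
    """Logarithmic spiral around the leader:
    ``w4*|X* - X|*exp(b*l)*cos(2*pi*l) + 2*w1*(r4 + r5)*X*``."""
    x = np.asarray(x, dtype=float)
    leader = np.asarray(leader, dtype=float)
    dist = np.abs(leader - x)
    new = (
        draws.w4 * dist * math.exp(b * draws.l) * math.cos(2.0 * math.pi * draws.l)
        + 2.0 * draws.w1 * (draws.r4 + draws.r5) * leader
    )
    return _clip(new, lower, upper)


# ---------------------------------------------------------------------------
# Exploitation updates
# ---------------------------------------------------------------------------

def exploit_sentries(
    x: np.ndarray,
    s1: np.ndarray,
    s2: np.ndarray,
    s3: np.ndarray,
    a: float,
    rng: np.random.Generator,
    lower: np.ndarray,
    upper: np.ndarray,
    coefficient_draws: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> np.ndarray:
    """Sentry-guided update: each of the three best agents ("sentries")
    pulls the agent with its own fresh ``A_i``, ``C_i``; the three
    candidate positions are aggregated by their arithmetic mean.

    ``coefficient_draws`` can inject explicit ``(A_i, C_i)`` pairs for
    deterministic testing; by default they are drawn from ``rng``
    (per sentry: r1 vector then r2 vector).
    """
    x = np.asarray(x, dtype=float)
    sentries = [np.asarray(s, dtype=float) for s in (s1, s2, s3)]
    candidates = []
    for i, s in enumerate(sentries):
        if coefficient_draws is None:
            r1 = rng.random(x.shape[0])
            r2 = rng.random(x.shape[0])
            A_i = 2.0 * a * r1 - a
            C_i = 2.0 * r2
        else:
            A_i, C_i = coefficient_draws[i]
        candidates.append(s - A_i * np.abs(C_i * s - x))
    new = np.mean(candidates, axis=0)
    return _clip(new, lower, upper)


def exploit_flock(
    x: np.ndarray,
    flock1: np.ndarray,
    z: float,
    w: float,
    d_step: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
) -> np.ndarray:
    """Local search around a near-leader agent:
    ``X + D*(1 + z)*w*(X - X_flock1)`` with ``D`` a per-dimension
    uniform [0, 1] step supplied by the caller."""
    x = np.asarray(x, dtype=float)
    new = x + np.asarray(d_step, dtype=float) * (1.0 + z) * w * (
        x - np.asarray(flock1, dtype=float)
    )
    return _clip(new, lower, upper)


# ---------------------------------------------------------------------------
# Group dynamics, mutation
# ---------------------------------------------------------------------------

def resize_groups(pop: Population, cfg: GGOConfig, rng: np.random.Generator) -> Population:
    """Rebalance the exploration/exploitation split.

    Normally ``group_shift_per_iteration`` agents migrate from the
    exploration to the exploitation group; when the leader has stagnated
    for ``stagnation_threshold`` iterations the flow reverses (and the
    counter resets).  Group sizes never drop below ``min_group_size``
    and always sum to the population size.  Which agents carry which tag
    is reshuffled uniformly at random afterwards.
    """
    shift = cfg.group_shift_per_iteration
    if pop.stagnation_counter >= cfg.stagnation_threshold:
        moved = min(shift, pop.n2 - cfg.min_group_size)
        pop.n1 += moved
        pop.n2 -= moved
        pop.stagnation_counter = 0
    else:
        moved = min(shift, pop.n1 - cfg.min_group_size)
        pop.n1 -= moved
        pop.n2 += moved
    order = rng.permutation(pop.size)
    for rank, idx in enumerate(order):
        pop.agents[idx].group_tag = EXPLORATION if rank < pop.n1 else EXPLOITATION
    return pop


def mutate(
    x: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    lower: np.ndarray,
    upper: np.ndarray,
) -> np.ndarray:
    """Component-wise uniform redraw within bounds with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must lie in [0, 1]")
    x = np.asarray(x, dtype=float).copy()
    if rate == 0.0:
        return x
    hit = rng.random(x.shape[0]) < rate
    fresh = rng.uniform(lower, upper)
    x[hit] = fresh[hit]
    return x


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def _evaluate(objective: Callable[[np.ndarray], float], x: np.ndarray) -> float:
    value = float(objective(x))
    if not math.isfinite(value):
        raise RuntimeError(f"objective returned non-finite value {value!r} at position {x!r}")
    return value


def run_ggo(objective: Callable[[np.ndarray], float], cfg: GGOConfig) -> OptimizationResult:
    """Run the full GGO loop and return the best solution ever seen.

    Per iteration: refresh the schedules (``a`` linear, ``z``
    quadratic), update every agent with its group's strategy, mutate
    (sparing the current best agent), clip to bounds, re-evaluate,
    refresh the elitist leader and the stagnation counter, then resize
    and reshuffle the groups.

    Exploration strategy gate per agent: spiral if ``r3 >= 0.5``, else
    paddling when mean ``|A| >= 1``, else encircling of the leader.
    Exploitation gate: fair coin between the sentry update and flock
    local search.
    """
    rng = np.random.default_rng(cfg.seed)
    d = cfg.dimension
    lower, upper = cfg.lower_bounds, cfg.upper_bounds
    n = cfg.population_size

    positions = rng.uniform(lower, upper, size=(n, d))
    agents = [Agent(position=positions[i].copy(), fitness=_evaluate(objective, positions[i]))
              for i in range(n)]
    evaluations = n

    best_idx = int(np.argmin([ag.fitness for ag in agents]))
    leader = Agent(position=agents[best_idx].position.copy(),
                   fitness=agents[best_idx].fitness)

    n1 = n // 2
    pop = Population(agents=agents, leader=leader, n1=n1, n2=n - n1)
    order = rng.permutation(n)
    for rank, idx in enumerate(order):
        agents[idx].group_tag = EXPLORATION if rank < pop.n1 else EXPLOITATION

    fitness_trace = np.empty(cfg.max_iterations)
    group_size_trace: list[tuple[int, int]] = []

    for t in range(cfg.max_iterations):
        a = a_schedule(t, cfg.max_iterations, cfg.a_start, cfg.a_end)
        z = z_schedule(t, cfg.max_iterations)
        r1_sched = r1_schedule(t, cfg.max_iterations, cfg.schedule_constant)

        fitnesses = [ag.fitness for ag in pop.agents]
        current_best = int(np.argmin(fitnesses))

        # sentries: three best by current fitness, elitist leader included
        sentry_pool = [(ag.fitness, i, ag.position) for i, ag in enumerate(pop.agents)]
        sentry_pool.append((pop.leader.fitness, -1, pop.leader.position))
        sentry_pool.sort(key=lambda item: (item[0], item[1]))
        sentry_positions = [item[2] for item in sentry_pool[:3]]

        for i, agent in enumerate(pop.agents):
            draws = draw_coefficients(a, rng, cfg, dimension=d)
            draws.z = z
            draws.r1_sched = r1_sched
            if agent.group_tag == EXPLORATION:
                if draws.r3 >= 0.5:
                    new = explore_spiral(agent.position, pop.leader.position, draws,
                                         cfg.spiral_constant, lower, upper)
                elif float(np.mean(np.abs(draws.A))) >= 1.0:
                    others = [j for j in range(n) if j != i]
                    picks = rng.choice(others, size=3, replace=False)
                    new = explore_paddles(
                        agent.position,
                        pop.agents[picks[0]].position,
                        pop.agents[picks[1]].position,
                        pop.agents[picks[2]].position,
                        z, draws, lower, upper,
                    )
                else:
                    new = explore_leader(agent.position, pop.leader.position,
                                         draws, lower, upper)
            else:
                if rng.random() < 0.5:
                    new = exploit_sentries(agent.position, *sentry_positions,
                                           a=a, rng=rng, lower=lower, upper=upper)
                else:
                    group_mates = [
                        (ag.fitness, j, ag.position)
                        for j, ag in enumerate(pop.agents)
                        if ag.group_tag == EXPLOITATION and j != i
                    ]
                    if group_mates:
                        flock1 = min(group_mates, key=lambda it: (it[0], it[1]))[2]
                    else:
                        flock1 = pop.leader.position
                    d_step = rng.random(d)
                    new = exploit_flock(agent.position, flock1, z, draws.w1,
                                        d_step, lower, upper)
            if i != current_best:
                new = mutate(new, cfg.mutation_rate, rng, lower, upper)
            agent.position = _clip(new, lower, upper)
            agent.fitness = _evaluate(objective, agent.position)
            evaluations += 1

        iter_best = int(np.argmin([ag.fitness for ag in pop.agents]))
        if pop.agents[iter_best].fitness < pop.leader.fitness:
            pop.leader = Agent(position=pop.agents[iter_best].position.copy(),
                               fitness=pop.agents[iter_best].fitness)
            pop.stagnation_counter = 0
        else:
            pop.stagnation_counter += 1

        fitness_trace[t] = pop.leader.fitness
        resize_groups(pop, cfg, rng)
        group_size_trace.append((pop.n1, pop.n2))

    return OptimizationResult(
        best_position=pop.leader.position.copy(),
        best_fitness=pop.leader.fitness,
        fitness_trace=fitness_trace,
        group_size_trace=group_size_trace,
        evaluations=evaluations,
        seed_used=cfg.seed,
    )
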