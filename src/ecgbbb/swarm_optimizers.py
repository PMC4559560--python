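"""GA, PSO, BFO and hybrid BFPSO minimizers over box-bounded continuous spaces.

All four optimizers share one population representation (:class:`Agent`,
:class:`SwarmState`) and one contract: positions stay inside ``[lo, hi]``, the
global-best trace is non-increasing, and runs are bit-reproducible from the
config seed.

Bacterial foraging (BFO) models each candidate solution as an E. coli cell
alternating tumbles (a fresh uniformly random unit direction) with swims
(repeated fixed-length steps along that direction while fitness strictly
improves).  After ``Nc`` chemotactic sweeps the less-healthy half of the
population — health being the fitness accumulated over the epoch — is replaced
by duplicates of the healthier half, and occasional elimination-dispersal
events teleport cells uniformly into the box to escape stagnation.

The hybrid BFPSO keeps BFO's nested loop for local search but, after every
chemotactic sweep, nudges each cell with a particle-swarm velocity update
toward its personal best and the swarm's global best, adding PSO's fast global
pull to BFO's local random hill climbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

Objective = Callable[[np.ndarray], float]


@dataclass
class SwarmConfig:
    """Shared hyperparameters for GA / PSO / BFO / BFPSO.

    BFO-specific: ``n_chemotactic`` (Nc) sweeps per reproduction epoch,
    ``swim_length`` (Ns) maximum improving steps per tumble, ``n_reproduction``
    (Nre) epochs per dispersal event, ``n_elimination`` (Ned) dispersal events,
    ``p_eliminate`` (Ped) per-agent dispersal probability and ``step_size`` (C,
    default 0.1 of the box range).  PSO-specific: inertia decayed linearly
    ``omega_start -> omega_end``, cognitive/social weights ``c1``/``c2`` and a
    velocity clamp as a fraction of the range.  GA-specific: tournament
    selection, uniform crossover and per-gene Gaussian mutation.
    """

    population: int = 30
    dims: int = 2
    lo: float | Sequence[float] = -5.0
    hi: float | Sequence[float] = 5.0
    omega_start: float = 0.9
    omega_end: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    velocity_clamp: float = 0.2
    n_chemotactic: int = 50
    swim_length: int = 4
    n_reproduction: int = 4
    n_elimination: int = 2
    p_eliminate: float = 0.25
    step_size: float | Sequence[float] | None = None
    n_iterations: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    tournament_size: int = 3
    seed: int = 0
    max_evaluations: int | None = None
    pso_per_step: bool = False  # BFPSO: mutate after every chemotactic step, not sweep

    def __post_init__(self) -> None:
        if self.population < 2 or self.population % 2:
            raise ValueError("population must be an even integer >= 2")
        self.lo = np.broadcast_to(np.asarray(self.lo, dtype=float), (self.dims,)).copy()
        self.hi = np.broadcast_to(np.asarray(self.hi, dtype=float), (self.dims,)).copy()
        if np.any(self.lo >= self.hi):
            raise ValueError("lo must be < hi elementwise")
        if not 0.0 <= self.p_eliminate <= 1.0:
            raise ValueError("p_eliminate must be in [0, 1]")
        if self.swim_length < 0:
            raise ValueError("swim_length must be >= 0")
        for w in (self.omega_start, self.omega_end):
            if not 0.0 < w < 1.5:
                raise ValueError("inertia weights must lie in (0, 1.5)")
        if self.step_size is None:
            self.step_size = 0.1 * (self.hi - self.lo)
        self.step_size = np.broadcast_to(np.asarray(self.step_size, dtype=float), (self.dims,)).copy()
        if np.any(self.step_size <= 0):
            raise ValueError("step_size must be > 0")

    @property
    def range(self) -> np.ndarray:
        return self.hi - self.lo


@dataclass
class Agent:
    """One candidate solution: position, velocity, personal best and health."""

    position: np.ndarray
    velocity: np.ndarray
    fitness: float = np.inf
    pbest_position: np.ndarray | None = None
    pbest_fitness: float = np.inf
    health: float = 0.0


@dataclass
class SwarmState:
    """Population plus global best, evaluation counter and fitness trace."""

    agents: list[Agent]
    rng: np.random.Generator
    gbest_position: np.ndarray | None = None
    gbest_fitness: float = np.inf
    trace: list[float] = field(default_factory=list)
    evaluations: int = 0


# ---------------------------------------------------------------------------
# benchmark objectives

def rosenbrock(x: np.ndarray) -> float:
    """Rosenbrock valley: sum_i [100 (x_{i+1} - x_i^2)^2 + (x_i - 1)^2].

    Nonnegative, zero only at the all-ones point; the standard curved-valley
    benchmark (and the cell-signaling function quoted in the BFO literature).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("rosenbrock requires dimension >= 2")
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (x[:-1] - 1.0) ** 2))


def sphere(x: np.ndarray) -> float:
    """Sum of squares; minimum 0 at the origin."""
    x = np.asarray(x, dtype=float)
    return float(np.dot(x, x))


OBJECTIVES = {"sphere": sphere, "rosenbrock": rosenbrock}


# ---------------------------------------------------------------------------
# shared primitives

def _init_state(config: SwarmConfig) -> SwarmState:
    rng = np.random.default_rng(config.seed)
    agents = [
        Agent(
            position=rng.uniform(config.lo, config.hi),
            velocity=np.zeros(config.dims),
        )
        for _ in range(config.population)
    ]
    return SwarmState(agents=agents, rng=rng)


def _evaluate(agent: Agent, x: np.ndarray, objective: Objective, state: SwarmState) -> float:
    value = float(objective(x))
    if not np.isfinite(value):
        raise ValueError(f"objective returned non-finite value {value} at {x}")
    state.evaluations += 1
    if value < agent.pbest_fitness:
        agent.pbest_fitness = value
        agent.pbest_position = x.copy()
        if value < state.gbest_fitness:
            state.gbest_fitness = value
            state.gbest_position = x.copy()
    return value


def _budget_left(state: SwarmState, config: SwarmConfig) -> bool:
    return config.max_evaluations is None or state.evaluations < config.max_evaluations


def pso_velocity_update(
    velocity: np.ndarray,
    position: np.ndarray,
    pbest: np.ndarray,
    gbest: np.ndarray,
    omega: float,
    c1: float,
    c2: float,
    rng: np.random.Generator,
    clamp: np.ndarray | None = None,
) -> np.ndarray:
    """v' = w v + c1 phi1 (pbest - x) + c2 phi2 (gbest - x), elementwise clamped.

    phi1, phi2 are independent uniform(0,1) draws per dimension.
    """
    phi1 = rng.random(len(velocity))
    phi2 = rng.random(len(velocity))
    new = omega * velocity + c1 * phi1 * (pbest - position) + c2 * phi2 * (gbest - position)
    if clamp is not None:
        new = np.clip(new, -clamp, clamp)
    return new


def pso_position_update(
    position: np.ndarray,
    velocity: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """x' = x + v, clipped into the box; velocity zeroed on clipped dimensions."""
    raw = position + velocity
    clipped = np.clip(raw, lo, hi)
    velocity = np.where(raw == clipped, velocity, 0.0)
    return clipped, velocity


def tumble_direction(d: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform(-1,1) raw vector normalized to unit Euclidean length."""
    if d < 1:
        raise ValueError("dimension must be >= 1")
    while True:
        raw = rng.uniform(-1.0, 1.0, size=d)
        norm = float(np.sqrt(raw @ raw))
        if norm > 0.0:
            return raw / norm


def chemotaxis_move(
    agent: Agent,
    objective: Objective,
    step_size: np.ndarray,
    swim_length: int,
    rng: np.random.Generator,
    lo: np.ndarray,
    hi: np.ndarray,
    state: SwarmState,
    direction: np.ndarray | None = None,
) -> Agent:
    """One tumble then up to ``swim_length`` swims while fitness strictly improves.

    The tumble step is always taken (classic random hill climbing); each swim
    step repeats the same unit direction and is kept only if it strictly
    improves fitness — a failed swim evaluation is charged but the move is
    reverted.  Every displacement has Euclidean norm ``C`` before boundary
    clipping; health accumulates the fitness of every evaluation.
    """
    if direction is None:
        direction = tumble_direction(len(agent.position), rng)
    step = step_size * direction

    new_pos = np.clip(agent.position + step, lo, hi)
    value = _evaluate(agent, new_pos, objective, state)
    agent.position = new_pos
    agent.fitness = value
    agent.health += value

    for _ in range(swim_length):
        cand = np.clip(agent.position + step, lo, hi)
        cand_value = _evaluate(agent, cand, objective, state)
        agent.health += cand_value
        if cand_value < agent.fitness:
            agent.position = cand
            agent.fitness = cand_value
        else:
            break
    return agent


def reproduction(state: SwarmState) -> SwarmState:
    """Drop the less-healthy half, duplicate the healthier half in place.

    Lower accumulated health means healthier under minimization; ties break by
    agent index (stable sort).  Population size is conserved and all healths
    reset for the next epoch.
    """
    agents = state.agents
    if len(agents) % 2:
        raise ValueError("population must be even for reproduction")
    order = sorted(range(len(agents)), key=lambda i: (agents[i].health, i))
    survivors = [agents[i] for i in order[: len(agents) // 2]]
    new_agents: list[Agent] = []
    for a in survivors:
        a.health = 0.0
        clone = Agent(
            position=a.position.copy(),
            velocity=a.velocity.copy(),
            fitness=a.fitness,
            pbest_position=None if a.pbest_position is None else a.pbest_position.copy(),
            pbest_fitness=a.pbest_fitness,
            health=0.0,
        )
        new_agents.extend([a, clone])
    state.agents = new_agents
    return state


def elimination_dispersal(state: SwarmState, p_eliminate: float, rng: np.random.Generator,
                          lo: np.ndarray, hi: np.ndarray) -> SwarmState:
    """Re-initialize each agent uniformly in the box with probability Ped.

    Personal-best memory is retained, so the global best never worsens; the
    dispersed agent's fitness becomes stale (+inf) until its next evaluation.
    """
    if not 0.0 <= p_eliminate <= 1.0:
        raise ValueError("p_eliminate must be in [0, 1]")
    for agent in state.agents:
        if rng.random() < p_eliminate:
            agent.position = rng.uniform(lo, hi)
            agent.velocity = np.zeros_like(agent.position)
            agent.fitness = np.inf
    return state


# ---------------------------------------------------------------------------
# optimizers

def _bfo_core(objective: Objective, config: SwarmConfig, pso_mutate: bool):
    """Shared Ned x Nre x Nc nest of BFO; with ``pso_mutate`` it is BFPSO."""
    state = _init_state(config)
    total_sweeps = max(1, config.n_elimination * config.n_reproduction * config.n_chemotactic)
    sweep = 0
    for _ in range(config.n_elimination):
        for _ in range(config.n_reproduction):
            for _ in range(config.n_chemotactic):
                if not _budget_left(state, config):
                    break
                for agent in state.agents:
                    if not _budget_left(state, config):
                        break
                    chemotaxis_move(
                        agent, objective, config.step_size, config.swim_length,
                        state.rng, config.lo, config.hi, state,
                    )
                    if pso_mutate and config.pso_per_step:
                        _pso_mutate_agent(agent, state, config, sweep, total_sweeps)
                state.trace.append(state.gbest_fitness)
                if pso_mutate and not config.pso_per_step:
                    for agent in state.agents:
                        _pso_mutate_agent(agent, state, config, sweep, total_sweeps)
                sweep += 1
            reproduction(state)
        elimination_dispersal(state, config.p_eliminate, state.rng, config.lo, config.hi)
    return state.gbest_position, state.gbest_fitness, state


def _pso_mutate_agent(agent: Agent, state: SwarmState, config: SwarmConfig,
                      sweep: int, total_sweeps: int) -> None:
    if agent.pbest_position is None or state.gbest_position is None:
        return
    frac = sweep / max(1, total_sweeps - 1)
    omega = config.omega_start + (config.omega_end - config.omega_start) * min(1.0, frac)
    clamp = config.velocity_clamp * config.range
    agent.velocity = pso_velocity_update(
        agent.velocity, agent.position, agent.pbest_position, state.gbest_position,
        omega, config.c1, config.c2, state.rng, clamp,
    )
    agent.position, agent.velocity = pso_position_update(
        agent.position, agent.velocity, config.lo, config.hi,
    )
    # fitness is stale until the next chemotactic tumble re-evaluates it
    agent.fitness = np.inf


def bfo_optimize(objective: Objective, config: SwarmConfig):
    """Bacterial foraging: Ned x Nre x Nc chemotaxis, reproduction, dispersal.

    Returns ``(best_position, best_fitness, state)``; ``state.trace`` holds the
    global best after every chemotactic sweep and ``state.evaluations`` obeys
    ``S * Nc * (Ns + 1) * Nre * Ned``.
    """
    return _bfo_core(objective, config, pso_mutate=False)


def bfpso_optimize(objective: Objective, config: SwarmConfig):
    """Hybrid: BFO's chemotaxis nest plus a PSO pull after every sweep."""
    return _bfo_core(objective, config, pso_mutate=True)


def pso_optimize(objective: Objective, config: SwarmConfig):
    """Canonical global-best PSO with linearly decaying inertia."""
    state = _init_state(config)
    clamp = config.velocity_clamp * config.range
    for agent in state.agents:
        agent.fitness = _evaluate(agent, agent.position, objective, state)
    state.trace.append(state.gbest_fitness)
    for it in range(config.n_iterations):
        if not _budget_left(state, config):
            break
        frac = it / max(1, config.n_iterations - 1)
        omega = config.omega_start + (config.omega_end - config.omega_start) * frac
        for agent in state.agents:
            if not _budget_left(state, config):
                break
            agent.velocity = pso_velocity_update(
                agent.velocity, agent.position, agent.pbest_position, state.gbest_position,
                omega, config.c1, config.c2, state.rng, clamp,
            )
            agent.position, agent.velocity = pso_position_update(
                agent.position, agent.velocity, config.lo, config.hi,
            )
            agent.fitness = _evaluate(agent, agent.position, objective, state)
        state.trace.append(state.gbest_fitness)
    return state.gbest_position, state.gbest_fitness, state


def ga_optimize(objective: Objective, config: SwarmConfig):
    """Real-coded GA: tournament selection, uniform crossover, Gaussian mutation.

    Elitism of one; the trace records the best-so-far per generation and is
    therefore non-increasing.
    """
    state = _init_state(config)
    for agent in state.agents:
        agent.fitness = _evaluate(agent, agent.position, objective, state)
    state.trace.append(state.gbest_fitness)
    rng = state.rng
    sigma = 0.1 * config.range

    def tournament() -> Agent:
        k = min(config.tournament_size, len(state.agents))
        idx = rng.choice(len(state.agents), size=k, replace=False)
        best = min(idx, key=lambda i: (state.agents[i].fitness, i))
        return state.agents[best]

    for _ in range(config.n_iterations):
        if not _budget_left(state, config):
            break
        elite = min(state.agents, key=lambda a: a.fitness)
        children = [Agent(position=elite.position.copy(), velocity=np.zeros(config.dims),
                          fitness=elite.fitness, pbest_position=elite.position.copy(),
                          pbest_fitness=elite.fitness)]
        while len(children) < config.population:
            p1, p2 = tournament(), tournament()
            if rng.random() < config.crossover_rate:
                mask = rng.random(config.dims) < 0.5
                child = np.where(mask, p1.position, p2.position)
            else:
                child = p1.position.copy()
            mutate = rng.random(config.dims) < config.mutation_rate
            child = child + mutate * rng.normal(0.0, 1.0, config.dims) * sigma
            child = np.clip(child, config.lo, config.hi)
            children.append(Agent(position=child, velocity=np.zeros(config.dims)))
        for agent in children[1:]:
            if not _budget_left(state, config):
                agent.fitness = np.inf
                continue
            agent.fitness = _evaluate(agent, agent.position, objective, state)
        state.agents = children
        state.trace.append(state.gbest_fitness)
    return state.gbest_position, state.gbest_fitness, state


OPTIMIZERS = {
    "ga": ga_optimize,
    "pso": pso_optimize,
    "bfo": bfo_optimize,
    "bfpso": bfpso_optimize,
}
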