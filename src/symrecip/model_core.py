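"""Core domain types and population construction.

Symmetry-based reciprocity models direct cooperation towards the partner
most similar to oneself on a symmetrical, non-heritable trait: an arbitrary
tag drawn uniformly on [0, 1] (Tag model) or a position on a square toroidal
world (Proximity model).  This module holds the configuration and population
types shared by the single-generation and evolutionary engines, plus the
three primitive sampling operations every engine relies on: population
construction, per-act candidate sampling, and the per-step acting order.

All randomness flows through a single :class:`numpy.random.Generator`
created from the configured seed; given the same seed and configuration two
runs produce identical populations and identical full simulation traces.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ModelVariant",
    "StrategyMode",
    "Strategy",
    "ConfigurationError",
    "SimConfig",
    "EvoConfig",
    "Agent",
    "Population",
    "make_population",
    "sample_candidates",
    "step_order",
]


class ModelVariant(str, enum.Enum):
    """Which symmetry trait drives partner choice."""

    TAG = "TAG"
    PROXIMITY = "PROXIMITY"


class StrategyMode(str, enum.Enum):
    """Evolutionary strategy space: two discrete strategies or a continuous
    individual probability P of behaving as a choosing cooperator."""

    TWO_STRATEGY = "TWO_STRATEGY"
    CONTINUOUS = "CONTINUOUS"


class Strategy(enum.IntEnum):
    """Behavioral strategy of a single agent.

    ``CHOOSING_COOPERATIVE`` agents always cooperate, picking their recipient
    by the symmetry rule; ``SELFISH`` agents never cooperate but can receive;
    ``MIXED`` agents cooperate with fixed individual probability P per act.
    """

    SELFISH = 0
    CHOOSING_COOPERATIVE = 1
    MIXED = 2


class ConfigurationError(ValueError):
    """Raised when a configuration violates a type invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Parameterization of a single-generation run.

    Parameters
    ----------
    model_variant
        ``TAG`` or ``PROXIMITY``.
    population_size
        Number of agents N (constant throughout a run).
    n_candidates
        Candidate-set size k: how many randomly drawn other agents an actor
        compares before cooperating, ``1 <= k <= N - 1``.
    n_steps
        Steps per run; every agent acts exactly once per step.
    n_replicates
        Independent replicates, seeded ``seed + replicate_index``.
    world_size
        Side length L of the square toroidal world (Proximity model only).
    seed
        Root seed for the replicate-0 random stream.
    """

    model_variant: ModelVariant = ModelVariant.TAG
    population_size: int = 50
    n_candidates: int = 10
    n_steps: int = 1000
    n_replicates: int = 100
    world_size: float = 101.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_variant", ModelVariant(self.model_variant))
        _require(self.population_size >= 3, "population_size must be >= 3")
        _require(
            1 <= self.n_candidates <= self.population_size - 1,
            f"n_candidates must satisfy 1 <= k <= N-1 "
            f"(got k={self.n_candidates}, N={self.population_size})",
        )
        _require(self.n_steps >= 1, "n_steps must be >= 1")
        _require(self.n_replicates >= 1, "n_replicates must be >= 1")
        _require(self.world_size > 0, "world_size must be > 0")

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        return _config_from_dict(cls, data)

    def to_dict(self) -> dict:
        return _config_to_dict(self)

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)


@dataclasses.dataclass(frozen=True)
class EvoConfig(SimConfig):
    """Parameterization of a multi-generation evolutionary run.

    Adds to :class:`SimConfig` the fitness economy (benefit b per act
    received, cost c per act given, in fitness units), the strategy space,
    the initial composition — a ``(n_cooperators, n_selfish)`` pair summing
    to N in TWO_STRATEGY mode, a ``(mean, sd)`` pair of the initial normal
    distribution of P (clamped to [0, 1]) in CONTINUOUS mode — truncation
    selection intensity s (bottom ``floor(s*N)`` culled, top ``floor(s*N)``
    duplicated each generation) and the mutation process applied to
    duplicates: with probability ``mutation_rate`` a duplicate switches
    strategy (TWO_STRATEGY) or has ``mutation_effect`` added to or
    subtracted from P with equal probability, clamped to [0, 1]
    (CONTINUOUS).
    """

    benefit: float = 2.0
    cost: float = 1.0
    n_generations: int = 50
    strategy_mode: StrategyMode = StrategyMode.TWO_STRATEGY
    initial_composition: tuple[float, float] = (45, 5)
    mutation_rate: float = 0.1
    mutation_effect: float = 0.2
    selection_proportion: float = 0.2
    n_replicates: int = 30
    # Mutate every agent of the new generation instead of only the
    # duplicates created from the top fraction (off by default; the
    # non-overlapping-generations reading).
    mutate_all_offspring: bool = False
    # Restrict random-walk movement to agents that act cooperatively on
    # their turn (off by default: movement is part of the turn).
    move_only_actors: bool = False

    def __post_init__(self) -> None:
        super().__post_init__()
        object.__setattr__(self, "strategy_mode", StrategyMode(self.strategy_mode))
        comp = tuple(self.initial_composition)
        _require(len(comp) == 2, "initial_composition must be a pair")
        object.__setattr__(self, "initial_composition", comp)
        _require(self.benefit > 0, "benefit must be > 0")
        _require(self.cost > 0, "cost must be > 0")
        _require(self.n_generations >= 1, "n_generations must be >= 1")
        _require(0 <= self.mutation_rate <= 1, "mutation_rate must be in [0, 1]")
        _require(self.mutation_effect >= 0, "mutation_effect must be >= 0")
        _require(
            0 < self.selection_proportion <= 0.5,
            "selection_proportion must be in (0, 0.5]",
        )
        _require(
            math.floor(self.selection_proportion * self.population_size) >= 1,
            "selection_proportion too small: floor(s*N) must be >= 1",
        )
        if self.strategy_mode is StrategyMode.TWO_STRATEGY:
            n_coop, n_selfish = comp
            _require(
                float(n_coop).is_integer() and float(n_selfish).is_integer(),
                "TWO_STRATEGY initial_composition must be integer counts",
            )
            _require(
                n_coop >= 0
                and n_selfish >= 0
                and int(n_coop) + int(n_selfish) == self.population_size,
                f"initial_composition {comp} must be non-negative and sum "
                f"to population_size={self.population_size}",
            )
        else:
            _require(comp[1] >= 0, "initial P distribution sd must be >= 0")

    @property
    def n_selected(self) -> int:
        """Number of agents culled (and duplicated) each generation."""
        return math.floor(self.selection_proportion * self.population_size)

    @classmethod
    def from_dict(cls, data: dict) -> "EvoConfig":
        return _config_from_dict(cls, data)


def _config_from_dict(cls, data: dict):
    """Build a config from a flat key/value mapping; unknown keys error."""
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigurationError(
            f"unknown configuration key(s): {', '.join(sorted(unknown))}"
        )
    kwargs = dict(data)
    if "initial_composition" in kwargs:
        kwargs["initial_composition"] = tuple(kwargs["initial_composition"])
    try:
        return cls(**kwargs)
    except TypeError as exc:  # missing required key etc.
        raise ConfigurationError(str(exc)) from exc


def _config_to_dict(cfg) -> dict:
    out = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, enum.Enum):
            v = v.value
        elif isinstance(v, tuple):
            v = list(v)
        out[f.name] = v
    return out


class Agent:
    """View of one agent inside a :class:`Population`.

    Attribute reads and writes go straight to the population's arrays, so an
    ``Agent`` is a live proxy, not a snapshot.  ``fitness`` is always the
    difference between accumulated benefits and accumulated costs.
    """

    __slots__ = ("_pop", "id")

    def __init__(self, pop: "Population", agent_id: int):
        self._pop = pop
        self.id = int(agent_id)

    # -- heritable / behavioral state ------------------------------------
    @property
    def strategy(self) -> Strategy:
        return Strategy(int(self._pop.strategy[self.id]))

    @strategy.setter
    def strategy(self, value: Strategy) -> None:
        self._pop.strategy[self.id] = int(value)

    @property
    def coop_probability(self) -> float:
        return float(self._pop.coop_probability[self.id])

    @coop_probability.setter
    def coop_probability(self, value: float) -> None:
        if not 0.0 <= value <= 1.0:
            raise ValueError("coop_probability must be in [0, 1]")
        self._pop.coop_probability[self.id] = value

    # -- symmetry traits --------------------------------------------------
    @property
    def tag(self) -> float:
        return float(self._pop.tag[self.id])

    @tag.setter
    def tag(self, value: float) -> None:
        if not 0.0 <= value <= 1.0:
            raise ValueError("tag must be in [0, 1]")
        self._pop.tag[self.id] = value

    @property
    def position(self) -> tuple[float, float]:
        return (float(self._pop.position[self.id, 0]), float(self._pop.position[self.id, 1]))

    @position.setter
    def position(self, value: Sequence[float]) -> None:
        self._pop.position[self.id] = value

    # -- fitness tallies --------------------------------------------------
    @property
    def benefit_accrued(self) -> float:
        return float(self._pop.benefit_accrued[self.id])

    @benefit_accrued.setter
    def benefit_accrued(self, value: float) -> None:
        self._pop.benefit_accrued[self.id] = value

    @property
    def cost_accrued(self) -> float:
        return float(self._pop.cost_accrued[self.id])

    @cost_accrued.setter
    def cost_accrued(self, value: float) -> None:
        self._pop.cost_accrued[self.id] = value

    @property
    def fitness(self) -> float:
        return self.benefit_accrued - self.cost_accrued

    def __repr__(self) -> str:
        return f"Agent(id={self.id}, strategy={self.strategy.name})"


class Population:
    """Ordered collection of N agents, stored column-wise for speed.

    Arrays are indexed by agent id (ids are exactly ``0..N-1``); N is
    constant across steps and generations.  ``agent(i)`` returns a live
    :class:`Agent` proxy into these arrays.
    """

    __slots__ = (
        "strategy",
        "coop_probability",
        "tag",
        "position",
        "benefit_accrued",
        "cost_accrued",
        "mutation_origin",
        "generation_index",
    )

    def __init__(self, n: int, generation_index: int = 0):
        self.strategy = np.full(n, int(Strategy.CHOOSING_COOPERATIVE), dtype=np.int8)
        self.coop_probability = np.ones(n, dtype=np.float64)
        self.tag = np.zeros(n, dtype=np.float64)
        self.position = np.zeros((n, 2), dtype=np.float64)
        self.benefit_accrued = np.zeros(n, dtype=np.float64)
        self.cost_accrued = np.zeros(n, dtype=np.float64)
        # Generation at which the agent's heritable payload was created by a
        # mutation event (lineage-inherited by clones); -1 for founder
        # lineages.  Lets analyses separate sustained strategies from
        # transient mutation flicker.
        self.mutation_origin = np.full(n, -1, dtype=np.int64)
        self.generation_index = generation_index

    @property
    def size(self) -> int:
        return self.strategy.shape[0]

    def __len__(self) -> int:
        return self.size

    def agent(self, agent_id: int) -> Agent:
        if not 0 <= agent_id < self.size:
            raise IndexError(f"agent id {agent_id} out of range 0..{self.size - 1}")
        return Agent(self, agent_id)

    @property
    def agents(self) -> list[Agent]:
        return [Agent(self, i) for i in range(self.size)]

    def __iter__(self) -> Iterator[Agent]:
        return iter(self.agents)

    @property
    def fitness(self) -> np.ndarray:
        return self.benefit_accrued - self.cost_accrued

    def reset_tallies(self) -> None:
        self.benefit_accrued[:] = 0.0
        self.cost_accrued[:] = 0.0

    def n_by_strategy(self, strategy: Strategy) -> int:
        return int(np.count_nonzero(self.strategy == int(strategy)))

    def copy(self) -> "Population":
        out = Population(self.size, self.generation_index)
        out.strategy[:] = self.strategy
        out.coop_probability[:] = self.coop_probability
        out.tag[:] = self.tag
        out.position[:] = self.position
        out.benefit_accrued[:] = self.benefit_accrued
        out.cost_accrued[:] = self.cost_accrued
        out.mutation_origin[:] = self.mutation_origin
        return out


def make_population(config: SimConfig, rng: np.random.Generator) -> Population:
    """Create the initial population for ``config``.

    Tags (Tag models) are independent uniforms on [0, 1]; positions
    (Proximity models) independent uniforms on [0, L)^2.  In TWO_STRATEGY
    mode exactly the configured counts of each strategy are created (ids
    0..n_coop-1 cooperative; shuffling is unnecessary because every engine
    treats ids symmetrically); in CONTINUOUS mode every agent is MIXED with
    P drawn from Normal(mean, sd) and clamped to [0, 1].  All fitness
    tallies start at zero.
    """
    n = config.population_size
    pop = Population(n)
    if config.model_variant is ModelVariant.TAG:
        pop.tag[:] = rng.random(n)
    else:
        pop.position[:] = rng.random((n, 2)) * config.world_size
    if isinstance(config, EvoConfig):
        if config.strategy_mode is StrategyMode.TWO_STRATEGY:
            n_coop = int(config.initial_composition[0])
            pop.strategy[:n_coop] = int(Strategy.CHOOSING_COOPERATIVE)
            pop.strategy[n_coop:] = int(Strategy.SELFISH)
            pop.coop_probability[:n_coop] = 1.0
            pop.coop_probability[n_coop:] = 0.0
        else:
            mean, sd = config.initial_composition
            pop.strategy[:] = int(Strategy.MIXED)
            pop.coop_probability[:] = np.clip(rng.normal(mean, sd, size=n), 0.0, 1.0)
    return pop


def sample_candidates(
    pop: Population, actor_id: int, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw k distinct candidate ids uniformly among all agents but the actor.

    Candidates are re-drawn independently for every act; strategy plays no
    role in eligibility.
    """
    n = pop.size
    if not 1 <= k <= n - 1:
        raise ConfigurationError(
            f"cannot sample k={k} candidates from {n - 1} other agents"
        )
    base = rng.choice(n - 1, size=k, replace=False)
    return base + (base >= actor_id)


def step_order(pop: Population, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of agent ids: the acting order for one step."""
    return rng.permutation(pop.size)
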