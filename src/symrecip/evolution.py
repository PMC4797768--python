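"""Multi-generation evolutionary engine.

Each generation repeats the single-generation interaction phase with two
changes: agents first decide whether to act at all (SELFISH agents never
do; MIXED agents act with their fixed individual probability P), and each
cooperative act costs the actor ``c`` fitness units while granting the
recipient ``b``.  Fitness is the accumulated benefit minus accumulated
cost over the generation.  Truncation selection then removes the
``floor(s*N)`` lowest-fitness agents and duplicates the ``floor(s*N)``
highest-fitness ones (fitness ties broken uniformly at random), mutating
each duplicate with probability ``mutation_rate``.  Tags and positions are
re-drawn uniformly for every agent at the start of each new generation —
the symmetry trait is not heritable and carries no information about
cooperativeness — and all fitness tallies reset to zero.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import _engine
from .model_core import (
    Agent,
    EvoConfig,
    ModelVariant,
    Population,
    Strategy,
    StrategyMode,
    make_population,
)
from .single_gen import SociometricMatrix

__all__ = [
    "act_or_abstain",
    "accrue",
    "run_generation",
    "select_and_reproduce",
    "EvolutionTrajectory",
    "run_evolution",
    "run_evolution_replicates",
    "write_trajectories",
]

_TRAJECTORY_COLUMNS = [
    "replicate",
    "generation",
    "n_cooperators",
    "n_selfish",
    "mean_P",
    "sd_P",
    "mean_fitness_coop",
    "mean_fitness_selfish",
    "mean_fitness",
    "n_acts",
    "n_mutations",
    "n_recent_mutant_cooperators",
]


def act_or_abstain(
    agent: Agent, mode: StrategyMode, rng: np.random.Generator
) -> bool:
    """Does this agent behave as a choosing cooperator on this act?

    TWO_STRATEGY agents follow their fixed strategy; MIXED agents draw
    independently per act, cooperating with probability exactly P.
    """
    if StrategyMode(mode) is StrategyMode.TWO_STRATEGY:
        return agent.strategy is Strategy.CHOOSING_COOPERATIVE
    return rng.random() < agent.coop_probability


def accrue(actor: Agent, recipient: Agent, b: float, c: float) -> None:
    """Book one cooperative act: actor pays c, recipient gains b."""
    if actor.id == recipient.id:
        raise ValueError("an agent cannot direct cooperation at itself")
    actor.cost_accrued += c
    recipient.benefit_accrued += b


def run_generation(
    pop: Population, config: EvoConfig, rng: np.random.Generator
) -> SociometricMatrix:
    """One generation's interaction phase; mutates fitness tallies in place.

    Abstaining agents neither choose nor pay but remain eligible as
    candidates and recipients; candidate sampling ignores strategy.
    """
    if np.any(pop.benefit_accrued != 0) or np.any(pop.cost_accrued != 0):
        raise ValueError("fitness tallies must be zero at generation start")
    if config.model_variant is ModelVariant.TAG:
        counts = _engine.run_tag_phase(pop, config, rng, accrue_fitness=True)
    else:
        counts = _engine.run_proximity_phase(pop, config, rng, accrue_fitness=True)
    m = SociometricMatrix(counts)
    m.validate()
    return m


def select_and_reproduce(
    pop: Population, config: EvoConfig, rng: np.random.Generator
) -> Population:
    """Truncation selection + reproduction with mutation; returns the next
    generation (size N, fresh tags/positions, zeroed tallies)."""
    new_pop, _ = _select_and_reproduce(pop, config, rng)
    return new_pop


def _select_and_reproduce(
    pop: Population, config: EvoConfig, rng: np.random.Generator
) -> tuple[Population, int]:
    n = pop.size
    m = config.n_selected
    fitness = pop.fitness
    # Ascending fitness; random keys break the (common) ties at zero.
    order = np.lexsort((rng.random(n), fitness))
    survivors = order[m:]  # bottom m culled
    parents = order[n - m :]  # top m duplicated
    survivors = np.sort(survivors)  # stable id layout: survivors then clones

    new_pop = Population(n, generation_index=pop.generation_index + 1)
    src = np.concatenate([survivors, parents])
    new_pop.strategy[:] = pop.strategy[src]
    new_pop.coop_probability[:] = pop.coop_probability[src]
    new_pop.mutation_origin[:] = pop.mutation_origin[src]

    continuous = config.strategy_mode is StrategyMode.CONTINUOUS
    if config.mutate_all_offspring:
        mut_idx = np.arange(n)
    else:
        mut_idx = np.arange(n - m, n)  # the m clones
    hit = mut_idx[rng.random(mut_idx.size) < config.mutation_rate]
    if continuous:
        signs = np.where(rng.random(hit.size) < 0.5, 1.0, -1.0)
        p = new_pop.coop_probability
        p[hit] = np.clip(p[hit] + signs * config.mutation_effect, 0.0, 1.0)
    else:
        s = new_pop.strategy
        s[hit] = np.where(
            s[hit] == int(Strategy.CHOOSING_COOPERATIVE),
            int(Strategy.SELFISH),
            int(Strategy.CHOOSING_COOPERATIVE),
        )
        new_pop.coop_probability[:] = (
            new_pop.strategy == int(Strategy.CHOOSING_COOPERATIVE)
        ).astype(float)
    new_pop.mutation_origin[hit] = new_pop.generation_index

    # Non-heritable symmetry trait: re-drawn for everyone each generation.
    if config.model_variant is ModelVariant.TAG:
        new_pop.tag[:] = rng.random(n)
    else:
        new_pop.position[:] = rng.random((n, 2)) * config.world_size
    return new_pop, int(hit.size)


@dataclasses.dataclass
class EvolutionTrajectory:
    """Per-generation record of one evolutionary replicate.

    Composition columns (strategy counts or P moments) describe the
    population at the start of each generation, before interactions;
    fitness columns summarize that generation's interaction phase.
    """

    records: pd.DataFrame
    replicate: int = 0

    @property
    def n_generations(self) -> int:
        return len(self.records)

    @property
    def final(self) -> pd.Series:
        return self.records.iloc[-1]


def run_evolution(
    config: EvoConfig, replicate: int = 0, matrix_hook=None
) -> EvolutionTrajectory:
    """Run one evolutionary replicate, seeded ``config.seed + replicate``.

    ``matrix_hook(generation, matrix)``, when given, receives each
    generation's sociometric matrix (e.g. for optional dumping).
    """
    rng = np.random.default_rng(config.seed + replicate)
    pop = make_population(config, rng)
    two_strategy = config.strategy_mode is StrategyMode.TWO_STRATEGY
    rows = []
    for gen in range(config.n_generations):
        row: dict = {"replicate": replicate, "generation": gen}
        if two_strategy:
            row["n_cooperators"] = pop.n_by_strategy(Strategy.CHOOSING_COOPERATIVE)
            row["n_selfish"] = pop.n_by_strategy(Strategy.SELFISH)
            row["mean_P"] = np.nan
            row["sd_P"] = np.nan
            # Cooperators whose lineage arose by mutation within the last
            # two generations: transient flicker, not sustained cooperation.
            coop_now = pop.strategy == int(Strategy.CHOOSING_COOPERATIVE)
            row["n_recent_mutant_cooperators"] = int(
                np.count_nonzero(coop_now & (pop.mutation_origin >= gen - 1))
            )
        else:
            row["n_cooperators"] = np.nan
            row["n_selfish"] = np.nan
            row["mean_P"] = float(pop.coop_probability.mean())
            row["sd_P"] = float(pop.coop_probability.std())
            row["n_recent_mutant_cooperators"] = np.nan
        matrix = run_generation(pop, config, rng)
        fitness = pop.fitness
        if two_strategy:
            coop = pop.strategy == int(Strategy.CHOOSING_COOPERATIVE)
            row["mean_fitness_coop"] = float(fitness[coop].mean()) if coop.any() else np.nan
            row["mean_fitness_selfish"] = (
                float(fitness[~coop].mean()) if (~coop).any() else np.nan
            )
        else:
            row["mean_fitness_coop"] = np.nan
            row["mean_fitness_selfish"] = np.nan
        row["mean_fitness"] = float(fitness.mean())
        row["n_acts"] = int(matrix.counts.sum())
        if matrix_hook is not None:
            matrix_hook(gen, matrix)
        pop, n_mut = _select_and_reproduce(pop, config, rng)
        row["n_mutations"] = n_mut
        rows.append(row)
    return EvolutionTrajectory(
        pd.DataFrame(rows, columns=_TRAJECTORY_COLUMNS), replicate=replicate
    )


def run_evolution_replicates(config: EvoConfig) -> list[EvolutionTrajectory]:
    """All ``config.n_replicates`` replicates, independently seeded."""
    return [run_evolution(config, i) for i in range(config.n_replicates)]


def write_trajectories(path, trajectories: list[EvolutionTrajectory]) -> None:
    """One CSV row per generation per replicate."""
    pd.concat([t.records for t in trajectories], ignore_index=True).to_csv(
        path, index=False
    )
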