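"""Interaction-phase engines shared by the single-generation and
evolutionary models.

The Tag-model phase is vectorized over actors within each step: the tag
choice rule consults only tags, which never change within a generation, so
acts within a step are mutually independent and their order is immaterial.
The Proximity-model phase is sequential per actor within each step because
the actor moves before choosing and earlier movers' new positions are
visible to later actors in the same step (asynchronous update).

Random-stream call order (the reproducibility contract):

* Tag phase, per step: [CONTINUOUS acting draw,] candidate key matrix,
  tie-break key matrix.
* Proximity phase, per step: acting-order permutation, [CONTINUOUS acting
  draw,] heading vector, candidate key matrix; then one extra draw per act
  that hits an exact distance tie.
"""

from __future__ import annotations

import math

import numpy as np

from .model_core import EvoConfig, Population, SimConfig, Strategy, StrategyMode

_TWO_PI = 2.0 * math.pi


def candidate_matrix(
    n: int, k: int, actor_ids: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """For each actor, k distinct uniform candidate ids excluding the actor.

    Uniformity over k-subsets follows from ranking i.i.d. uniform keys.
    """
    keys = rng.random((actor_ids.size, n - 1))
    cand = np.argpartition(keys, k - 1, axis=1)[:, :k]
    return cand + (cand >= actor_ids[:, None])


def argmin_rows_tiebreak(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise argmin with exact ties broken uniformly at random."""
    m = values.min(axis=1, keepdims=True)
    keys = np.where(values == m, rng.random(values.shape), -1.0)
    return keys.argmax(axis=1)


def run_tag_phase(
    pop: Population,
    config: SimConfig,
    rng: np.random.Generator,
    *,
    accrue_fitness: bool = False,
) -> np.ndarray:
    """All steps of one Tag-model generation; returns the count matrix.

    With ``accrue_fitness`` (evolutionary models) each acting agent pays
    ``cost`` and its chosen recipient gains ``benefit``; SELFISH agents and
    MIXED agents failing their per-act P draw abstain but stay eligible as
    candidates.
    """
    n = pop.size
    k = config.n_candidates
    counts = np.zeros((n, n), dtype=np.int64)
    tags = pop.tag
    all_ids = np.arange(n)
    fixed_actors: np.ndarray | None = None
    continuous = False
    if accrue_fitness:
        evo: EvoConfig = config  # type: ignore[assignment]
        b, c = evo.benefit, evo.cost
        if evo.strategy_mode is StrategyMode.TWO_STRATEGY:
            fixed_actors = np.flatnonzero(pop.strategy == int(Strategy.CHOOSING_COOPERATIVE))
        else:
            continuous = True
    for _ in range(config.n_steps):
        if not accrue_fitness:
            actors = all_ids
        elif continuous:
            actors = np.flatnonzero(rng.random(n) < pop.coop_probability)
        else:
            actors = fixed_actors
        if actors.size == 0:
            continue
        cand = candidate_matrix(n, k, actors, rng)
        diffs = np.abs(tags[cand] - tags[actors][:, None])
        j = argmin_rows_tiebreak(diffs, rng)
        chosen = cand[np.arange(actors.size), j]
        np.add.at(counts, (actors, chosen), 1)
        if accrue_fitness:
            pop.cost_accrued[actors] += c
            np.add.at(pop.benefit_accrued, chosen, b)
    return counts


def run_proximity_phase(
    pop: Population,
    config: SimConfig,
    rng: np.random.Generator,
    *,
    accrue_fitness: bool = False,
) -> np.ndarray:
    """All steps of one Proximity-model generation; returns the count matrix.

    Sequential within each step: every agent, in a fresh random order, takes
    one unit random-walk step (all agents move on their turn unless
    ``move_only_actors``), then — if acting — cooperates with the toroidally
    nearest of k freshly sampled candidates, ties uniform at random.
    Positions are updated in place on ``pop``.
    """
    n = pop.size
    k = config.n_candidates
    L = config.world_size
    counts = np.zeros((n, n), dtype=np.int64)
    pos = pop.position
    continuous = False
    coop_mask: np.ndarray | None = None
    move_only_actors = False
    b = c = 0.0
    if accrue_fitness:
        evo: EvoConfig = config  # type: ignore[assignment]
        b, c = evo.benefit, evo.cost
        move_only_actors = evo.move_only_actors
        if evo.strategy_mode is StrategyMode.TWO_STRATEGY:
            coop_mask = pop.strategy == int(Strategy.CHOOSING_COOPERATIVE)
        else:
            continuous = True
    cost_accrued = pop.cost_accrued
    benefit_accrued = pop.benefit_accrued
    cos, sin = math.cos, math.sin
    for _ in range(config.n_steps):
        order = rng.permutation(n)
        if not accrue_fitness:
            acts = None
        elif continuous:
            acts = rng.random(n) < pop.coop_probability
        else:
            acts = coop_mask
        thetas = rng.random(n) * _TWO_PI
        keys = rng.random((n, n - 1))
        for a in order:
            a = int(a)
            acting = True if acts is None else bool(acts[a])
            if acting or not move_only_actors:
                th = thetas[a]
                x = (pos[a, 0] + cos(th)) % L
                y = (pos[a, 1] + sin(th)) % L
                pos[a, 0] = x
                pos[a, 1] = y
            else:
                x = pos[a, 0]
                y = pos[a, 1]
            if not acting:
                continue
            cand = np.argpartition(keys[a], k - 1)[:k]
            cand += cand >= a
            dx = np.abs(pos[cand, 0] - x)
            np.minimum(dx, L - dx, out=dx)
            dy = np.abs(pos[cand, 1] - y)
            np.minimum(dy, L - dy, out=dy)
            d2 = dx * dx + dy * dy
            j = int(np.argmin(d2))
            tied = np.flatnonzero(d2 == d2[j])
            if tied.size > 1:
                j = int(tied[int(rng.integers(tied.size))])
            ch = int(cand[j])
            counts[a, ch] += 1
            if accrue_fitness:
                cost_accrued[a] += c
                benefit_accrued[ch] += b
    return counts
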