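"""Evolutionary engine: acting decisions, fitness bookkeeping, truncation
selection with mutation, and population-level dynamics."""

import numpy as np
import pytest

from symrecip import (
    EvoConfig,
    Population,
    Strategy,
    StrategyMode,
    accrue,
    act_or_abstain,
    make_population,
    run_evolution,
    run_generation,
    select_and_reproduce,
)
from symrecip.evolution import _select_and_reproduce


def _pop_with_fitness(n, fitness, p=None):
    pop = Population(n)
    pop.strategy[:] = int(Strategy.MIXED)
    pop.coop_probability[:] = np.linspace(0, 1, n) if p is None else p
    pop.benefit_accrued[:] = np.maximum(fitness, 0)
    pop.cost_accrued[:] = np.maximum(-np.asarray(fitness, dtype=float), 0)
    return pop


class TestActOrAbstain:
    def test_fixed_strategies(self, rng):
        pop = Population(3)
        pop.strategy[:] = [
            int(Strategy.SELFISH),
            int(Strategy.CHOOSING_COOPERATIVE),
            int(Strategy.MIXED),
        ]
        selfish, coop, _ = pop.agents
        assert all(
            not act_or_abstain(selfish, StrategyMode.TWO_STRATEGY, rng)
            for _ in range(100)
        )
        assert all(
            act_or_abstain(coop, StrategyMode.TWO_STRATEGY, rng) for _ in range(100)
        )

    def test_mixed_boundary_probabilities(self, rng):
        pop = Population(2)
        pop.strategy[:] = int(Strategy.MIXED)
        pop.coop_probability[:] = [1.0, 0.0]
        always, never = pop.agents
        assert all(act_or_abstain(always, StrategyMode.CONTINUOUS, rng) for _ in range(200))
        assert not any(act_or_abstain(never, StrategyMode.CONTINUOUS, rng) for _ in range(200))

    def test_mixed_rate_matches_p(self, rng):
        pop = Population(1)
        pop.strategy[:] = int(Strategy.MIXED)
        pop.coop_probability[:] = 0.3
        agent = pop.agent(0)
        draws = sum(
            act_or_abstain(agent, StrategyMode.CONTINUOUS, rng) for _ in range(100_000)
        )
        assert 0.295 <= draws / 100_000 <= 0.305


class TestAccrue:
    def test_bookkeeping(self):
        pop = Population(2)
        actor, recipient = pop.agents
        accrue(actor, recipient, b=2.0, c=1.0)
        assert actor.fitness == -1.0
        assert recipient.fitness == 2.0
        # net population change is exactly b - c per act
        assert pop.fitness.sum() == pytest.approx(1.0)

    def test_ten_for_ten_arithmetic(self):
        pop = Population(2)
        a, r = pop.agents
        for _ in range(10):
            accrue(a, r, b=1.1, c=1.0)
            accrue(r, a, b=1.1, c=1.0)
        assert a.fitness == pytest.approx(10 * 1.1 - 10 * 1.0)

    def test_self_directed_act_rejected(self):
        pop = Population(2)
        with pytest.raises(ValueError):
            accrue(pop.agent(0), pop.agent(0), 2.0, 1.0)


class TestRunGeneration:
    @pytest.mark.parametrize("variant", ["TAG", "PROXIMITY"])
    def test_all_selfish_population_is_inert(self, variant, rng):
        cfg = EvoConfig(
            model_variant=variant,
            population_size=10,
            n_candidates=3,
            n_steps=20,
            initial_composition=(0, 10),
        )
        pop = make_population(cfg, rng)
        m = run_generation(pop, cfg, rng)
        assert m.counts.sum() == 0
        assert np.all(pop.fitness == 0)

    @pytest.mark.parametrize("variant", ["TAG", "PROXIMITY"])
    @pytest.mark.parametrize("mode,comp", [("TWO_STRATEGY", (7, 3)), ("CONTINUOUS", (0.5, 0.2))])
    def test_fitness_conservation(self, variant, mode, comp, rng):
        # Total population fitness after the interaction phase is exactly
        # (b - c) times the number of acts.
        cfg = EvoConfig(
            model_variant=variant,
            population_size=10,
            n_candidates=4,
            n_steps=30,
            benefit=2.5,
            cost=1.0,
            strategy_mode=mode,
            initial_composition=comp,
        )
        pop = make_population(cfg, rng)
        m = run_generation(pop, cfg, rng)
        acts = m.counts.sum()
        assert pop.fitness.sum() == pytest.approx((2.5 - 1.0) * acts)

    def test_cooperators_act_every_step(self, rng):
        cfg = EvoConfig(
            population_size=10, n_candidates=3, n_steps=50, initial_composition=(7, 3)
        )
        pop = make_population(cfg, rng)
        m = run_generation(pop, cfg, rng)
        assert m.counts.sum() == 7 * 50
        coop_rows = m.counts[pop.strategy == int(Strategy.CHOOSING_COOPERATIVE)]
        assert np.all(coop_rows.sum(axis=1) == 50)

    def test_nonzero_tallies_rejected(self, rng):
        cfg = EvoConfig(population_size=10, n_candidates=3, initial_composition=(5, 5))
        pop = make_population(cfg, rng)
        pop.benefit_accrued[0] = 1.0
        with pytest.raises(ValueError):
            run_generation(pop, cfg, rng)


class TestSelectAndReproduce:
    def test_exact_cull_and_duplication(self, rng):
        # Distinct fitness values and mu=0: the bottom 10 payloads vanish,
        # the top 10 appear twice, the middle 30 appear once.
        cfg = EvoConfig(
            strategy_mode="CONTINUOUS",
            initial_composition=(0.5, 0.1),
            mutation_rate=0.0,
        )
        fitness = np.arange(50, dtype=float)
        p = np.linspace(0.01, 0.99, 50)
        pop = _pop_with_fitness(50, fitness, p)
        new = select_and_reproduce(pop, cfg, rng)
        assert new.size == 50
        expected = np.sort(np.concatenate([p[10:], p[40:]]))
        assert np.allclose(np.sort(new.coop_probability), expected)
        assert np.all(new.benefit_accrued == 0) and np.all(new.cost_accrued == 0)
        assert new.generation_index == pop.generation_index + 1

    def test_tags_redrawn_each_generation(self, rng):
        cfg = EvoConfig(initial_composition=(45, 5))
        pop = make_population(cfg, rng)
        old_tags = pop.tag.copy()
        new = select_and_reproduce(pop, cfg, rng)
        assert not np.array_equal(new.tag, old_tags)
        assert np.all((new.tag >= 0) & (new.tag <= 1))

    def test_all_selfish_absorbing_without_mutation(self):
        cfg = EvoConfig(
            population_size=10,
            n_candidates=3,
            n_steps=10,
            n_generations=5,
            initial_composition=(0, 10),
            mutation_rate=0.0,
        )
        traj = run_evolution(cfg, 0)
        assert (traj.records["n_cooperators"] == 0).all()

    def test_mutation_effect_clamped(self):
        # P = 0.95 mutated by +/-0.2 can only become 1.0 or 0.75.
        cfg = EvoConfig(
            population_size=5,
            n_candidates=2,
            strategy_mode="CONTINUOUS",
            initial_composition=(0.95, 0.0),
            mutation_rate=1.0,
            mutation_effect=0.2,
        )
        seen = set()
        for seed in range(40):
            pop = _pop_with_fitness(5, np.arange(5.0), p=np.full(5, 0.95))
            new = select_and_reproduce(pop, cfg, np.random.default_rng(seed))
            seen.update(np.round(new.coop_probability, 10).tolist())
        assert seen == {0.95, 1.0, 0.75}

    def test_mutation_provenance_stamped(self, rng):
        cfg = EvoConfig(
            population_size=10,
            n_candidates=3,
            initial_composition=(5, 5),
            mutation_rate=1.0,
        )
        pop = make_population(cfg, rng)
        pop.benefit_accrued[:] = np.arange(10.0)
        new, n_mut = _select_and_reproduce(pop, cfg, rng)
        assert n_mut == cfg.n_selected
        assert np.count_nonzero(new.mutation_origin == new.generation_index) == n_mut

    def test_mutate_all_offspring_flag(self, rng):
        cfg = EvoConfig(
            population_size=10,
            n_candidates=3,
            initial_composition=(5, 5),
            mutation_rate=1.0,
            mutate_all_offspring=True,
        )
        pop = make_population(cfg, rng)
        pop.benefit_accrued[:] = np.arange(10.0)
        new, n_mut = _select_and_reproduce(pop, cfg, rng)
        assert n_mut == 10


class TestRunEvolution:
    def test_trajectory_shape_and_invariants(self):
        cfg = EvoConfig(
            population_size=20,
            n_candidates=5,
            n_steps=50,
            n_generations=8,
            initial_composition=(15, 5),
            seed=1,
        )
        traj = run_evolution(cfg, 0)
        rec = traj.records
        assert len(rec) == 8
        assert (rec["n_cooperators"] + rec["n_selfish"] == 20).all()
        assert (rec["generation"] == np.arange(8)).all()

    def test_continuous_trajectory_bounds(self):
        cfg = EvoConfig(
            population_size=20,
            n_candidates=5,
            n_steps=50,
            n_generations=8,
            strategy_mode="CONTINUOUS",
            initial_composition=(0.5, 0.2),
            seed=1,
        )
        rec = run_evolution(cfg, 0).records
        assert rec["mean_P"].between(0, 1).all()
        assert (rec["sd_P"] >= 0).all()

    def test_move_only_actors_flag_runs(self):
        cfg = EvoConfig(
            model_variant="PROXIMITY",
            population_size=10,
            n_candidates=3,
            n_steps=20,
            n_generations=3,
            initial_composition=(5, 5),
            move_only_actors=True,
            seed=2,
        )
        traj = run_evolution(cfg, 0)
        assert len(traj.records) == 3

    def test_replicates_differ(self):
        cfg = EvoConfig(
            population_size=20,
            n_candidates=5,
            n_steps=100,
            n_generations=10,
            initial_composition=(15, 5),
            seed=3,
        )
        t0 = run_evolution(cfg, 0).records["n_cooperators"]
        t1 = run_evolution(cfg, 1).records["n_cooperators"]
        assert not t0.equals(t1)


class TestSelectionVersusDrift:
    def test_cost_bearing_is_disadvantageous_even_when_benefit_equals_cost(self):
        # Truncation selection acts on fitness ranks, and a cooperator's
        # rank key is received - (c/b) * n_steps while a selfish agent's is
        # just received: cooperators are selected against for any c > 0,
        # including b = c (total fitness is conserved then, but the cost is
        # individual while the benefit goes to others).  The disadvantage
        # shrinks as b/c grows, because benefit variance swamps the fixed
        # cost.  Scaled problem sizes (100 steps, 20 generations).
        def final_counts(benefit, n_reps):
            cfg = EvoConfig(
                population_size=50,
                n_candidates=10,
                n_steps=100,
                n_generations=20,
                benefit=benefit,
                cost=1.0,
                initial_composition=(25, 25),
                mutation_rate=0.0,
                seed=17,
            )
            return np.array(
                [run_evolution(cfg, r).final["n_cooperators"] for r in range(n_reps)]
            )

        equal = final_counts(1.0, 40)
        high = final_counts(500.0, 40)
        assert np.all(equal == 0)  # b = c still drives extinction
        assert high.mean() > equal.mean()  # selection weakens with b/c

    def test_mean_cooperator_count_declines_monotonically(self):
        # Replicate-mean trajectory is non-increasing after the initial
        # transient, within sampling error.
        cfg = EvoConfig(
            population_size=50,
            n_candidates=10,
            n_steps=200,
            n_generations=40,
            benefit=2.0,
            cost=1.0,
            initial_composition=(45, 5),
            seed=23,
        )
        counts = np.array(
            [run_evolution(cfg, r).records["n_cooperators"].to_numpy() for r in range(10)]
        )
        mean = counts.mean(axis=0)
        diffs = np.diff(mean[5:])
        assert np.all(diffs <= 1.5)
        assert mean[-1] < mean[5]
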