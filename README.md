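# symrecip

Agent-based models of **symmetry-based reciprocity** — the hypothesis that
animals reciprocate cooperation not by keeping score, but simply by
directing cooperative acts at the partner most similar to themselves on a
symmetrical trait. Because similarity is symmetrical (if A is the closest
match of B, B is among the closest matches of A), partner choice alone can
generate mutual, "apparently reciprocal" exchange without any memory of
past interactions.

The package is for researchers in behavioral ecology and the evolution of
cooperation who want to simulate these dynamics, analyze the resulting
cooperation networks, and probe whether such partner-choice rules can
survive natural selection.

## Models

Two symmetry traits are implemented, each in a single-generation and a
multi-generation evolutionary variant:

* **Tag model** — each agent carries a non-heritable tag drawn uniformly on
  [0, 1]. An actor samples k random candidates and cooperates with the one
  minimizing |tag_actor − tag_candidate| (ties uniform at random).
* **Proximity model** — agents live on an L×L toroidal world (default
  101×101). An actor first takes a unit-length random-walk step in a
  uniformly random heading, then cooperates with the toroidally nearest of
  k random candidates.

In single-generation runs all N agents act once per step for n_steps steps
and always cooperate; the output is the N×N **sociometric matrix** of acts
given. In evolutionary runs each act costs the actor c fitness units and
grants the recipient b; agents are either *choosing cooperators* vs.
*selfish* (two-strategy mode) or carry a fixed individual probability P of
cooperating per act (continuous mode). Each generation ends with
**truncation selection**: the ⌊sN⌋ lowest-fitness agents are removed, the
⌊sN⌋ highest-fitness agents are duplicated, duplicates mutate with
probability μ (strategy switch, or P ± δ clamped to [0, 1]), and every
tag/position is re-drawn — the symmetry trait is not heritable and carries
no information about cooperativeness.

The analysis layer computes the statistics used to characterize such
models: the within-subject regression/correlation of cooperation given on
cooperation received (per agent, across partners), Freeman degree
centralization, and Newman weighted modularity Q under a greedy community
partition, plus GraphML/CSV export.

## Worked example

```python
import numpy as np
from symrecip import (SimConfig, EvoConfig, run_single_generation,
                      run_evolution, given_received_regression,
                      degree_centralization, modularity)

cfg = SimConfig(model_variant="TAG", population_size=50, n_candidates=10,
                n_steps=1000, seed=1)
m = run_single_generation(cfg, np.random.default_rng(cfg.seed))
rep = given_received_regression(m)
net = modularity(m)
print(f"mean within-subject pearson r: {rep.mean_r:.3f}")
print(f"degree centralization: {degree_centralization(m):.3f}")
print(f"modularity Q: {net.modularity_Q:.3f} ({net.n_communities} communities)")
```

prints

```
mean within-subject pearson r: 0.927
degree centralization: 0.175
modularity Q: 0.621 (5 communities)
```

Every agent's cooperation given is strongly correlated with cooperation
received (mean r ≈ 0.93) even though no agent tracks what it receives —
the symmetry of the tag rule alone produces reciprocity — and the network
splits into well-separated clusters of preferred partners (Q ≈ 0.62).

Adding selection changes the picture:

```python
evo = EvoConfig(model_variant="TAG", population_size=50, n_candidates=10,
                n_steps=1000, benefit=2.0, cost=1.0, n_generations=50,
                initial_composition=(45, 5), seed=1)
traj = run_evolution(evo, replicate=0)
print(traj.records.loc[[0, 5, 10, 49],
      ["generation", "n_cooperators", "mean_fitness_coop", "mean_fitness_selfish"]])
```

```
 generation  n_cooperators  mean_fitness_coop  mean_fitness_selfish
          0             45         746.844444           2278.400000
          5              6        -839.333333            250.818182
         10              1       -1000.000000             40.816327
         49              1       -1000.000000             40.816327
```

Cooperators pay the cost of every act while benefits flow to recipients
regardless of strategy, so selfish agents have higher fitness from the
start and cooperators collapse from 45/50 to a residue of transient
mutants within ~10 generations (the trajectory column
`n_recent_mutant_cooperators` separates such mutation flicker from
sustained cooperation).

## Command line

```bash
symrecip run-single config.yaml --out out/        # matrices + analyses
symrecip run-evolution evo.yaml --out out/        # trajectory table
symrecip sweep sweep.yaml --out out/              # parameter-grid outcomes
symrecip analyze out/matrix-000.csv               # stats for one matrix
```

Config files are flat YAML/JSON documents whose keys match the
`SimConfig`/`EvoConfig` field names; unknown or missing keys produce an
error naming the offending key. All outputs are a pure function of the
configuration and seed.

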