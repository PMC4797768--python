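# Methods

## Model

A population of N agents interacts for `n_steps` steps per generation.
Each step, every agent acts exactly once. An act consists of: (optionally)
deciding whether to cooperate at all, sampling k candidates uniformly
without replacement from the other N−1 agents (strategy plays no role in
eligibility), and directing one cooperative act at the candidate selected
by the symmetry rule:

* **Tag rule** — minimize |tag_actor − tag_candidate|; tags are i.i.d.
  uniform on [0, 1].
* **Proximity rule** — the actor first moves one unit length in a
  continuous uniform heading θ ∈ [0, 2π) on the L×L torus (per-axis
  wrap-around; axis separation min(|Δ|, L−|Δ|)), then minimizes toroidal
  Euclidean distance.

Exact ties are broken uniformly at random in both rules. Candidates are
re-sampled independently for every act. Agents hold no memory of past
interactions; nothing in either rule consults cooperation received.

In evolutionary runs an act costs the actor `cost` (c) fitness units and
grants the recipient `benefit` (b); fitness is accumulated benefit minus
accumulated cost over the generation. Abstaining agents (selfish agents
always; mixed agents with probability 1−P per act) neither choose nor pay
but remain eligible as candidates and recipients. After the interaction
phase, truncation selection removes the ⌊sN⌋ lowest-fitness agents and
duplicates the ⌊sN⌋ highest-fitness ones (fitness ties broken uniformly at
random — ties are common because many agents finish at exactly zero).
Each duplicate mutates with probability μ: a strategy switch in
two-strategy mode, or P ± δ (sign equiprobable, result clamped to [0, 1])
in continuous mode. Tags and positions are re-drawn uniformly for every
agent each generation: the symmetry trait is explicitly non-heritable, and
re-randomizing positions removes any spatial kin structure.

## Default parameters

| parameter | symbol | default | notes |
|---|---|---|---|
| population size | N | 50 | constant across steps and generations |
| candidate-set size | k | 10 | 1 ≤ k ≤ N−1; grid values 2/10/25/49 |
| steps per generation | — | 1000 | each agent acts once per step |
| world side | L | 101 | torus, continuous coordinates (units = cells) |
| benefit per act | b | 2 | fitness units; grid values 1.1/2/5/50 |
| cost per act | c | 1 | fitness units |
| generations | — | 50 (two-strategy), 200 (continuous) | |
| selection proportion | s | 0.2 | ⌊sN⌋ = 10 culled and duplicated |
| mutation rate | μ | 0.1 | per duplicate |
| mutation effect | δ | 0.2 | continuous mode only |
| initial composition | — | (45, 5) or (mean, sd) of P | two-strategy / continuous |

Initial P values are drawn Normal(mean, sd) and clamped to [0, 1]: P is a
probability and must satisfy its domain invariant; for the (0.95, 0.05)
and (0.05, 0.05) starts the clamp affects a small tail mass, and for
(0.5, 0.35) it is symmetric and leaves the mean at 0.5.

## Scheduling and randomness

Within a step, acts in the Tag model are mutually independent (the choice
rule consults only tags, which are fixed within a generation), so the Tag
interaction phase is vectorized per step and the acting order is
immaterial. The Proximity phase is asynchronous in the strict sense:
agents act sequentially in a fresh uniform random order each step, and the
new position of an earlier mover is visible to later actors in the same
step. All agents move on their turn whether or not they cooperate
(movement is part of the turn; the `move_only_actors` flag restricts
movement to acting agents for sensitivity analysis).

All randomness flows through one `numpy.random.Generator` per replicate,
seeded `seed + replicate_index`; the per-step call order is fixed and
documented in `symrecip/_engine.py`, making every trace reproducible from
the configuration alone. Parameter-sweep cells derive seeds by hashing
(root seed, cell index, replicate index) so partial re-runs reproduce
exactly. Candidate sets are sampled by ranking i.i.d. uniform keys, which
is uniform over k-subsets.

Mutation is applied to the ⌊sN⌋ duplicates only (the reproduction event);
the `mutate_all_offspring` flag exposes the alternative non-overlapping-
generations reading in which every agent of the new generation is a fresh
offspring and mutates.

## Trajectory accounting

Trajectories record one row per generation: composition (strategy counts
or P moments) describes the population at the start of the generation,
before interactions; fitness summaries and act totals describe that
generation's interaction phase (fitness is identically zero before
interactions, so this is the only informative placement). Each agent
carries a lineage `mutation_origin` stamp — the generation at which its
heritable payload was created by a mutation event, inherited by clones —
and two-strategy trajectories report `n_recent_mutant_cooperators`, the
cooperators whose lineage arose within the last two generations. This
separates sustained cooperation from mutation flicker: with 10 duplicates
mutating at μ = 0.1, roughly one mutant enters per generation, so a
population in which the cooperative strategy is extinct still shows a
fluctuating handful of cooperators (≈ Binomial(10, 0.1) fresh mutants per
snapshot, occasionally 3 or more) that selection removes within a
generation or two.

## Analyses

*Given-vs-received regression.* For agent i the paired observations over
partners j ≠ i are (received_ij = m[j, i], given_ij = m[i, j]); we compute
the OLS slope of given on received and the Pearson correlation, exclude
agents with zero variance on either axis (counted and flagged), and
aggregate as the across-agent mean slope, mean r, fraction of positive r,
and a one-sample t test of r against zero. A pooled-dyad variant
(`pooled_dyad_regression`) is available. Raw counts are used: in
single-generation runs every agent gives exactly `n_steps` acts, so counts
and rates differ only by a constant.

*Centralization.* Freeman degree centralization Σᵢ(c_max − cᵢ) /
((N−1)(N−2)) on the symmetrized (w + wᵀ), binarized network: 1 for a star,
0 for any regular graph. The index named in the field is a family; the
Freeman degree form is the default, with a weighted-strength variant
(normalized by (N−1)·s_max) behind a flag.

*Modularity.* Newman weighted modularity on the symmetrized graph, with
the partition found by the deterministic greedy agglomerative (CNM)
optimizer from networkx. Greedy optimization is a heuristic: tests compare
it against a brute-force search over all 203 partitions of 6-node graphs
and assert the greedy Q never exceeds the optimum, reporting any
optimality gap (small gaps occur on unstructured random graphs; the
clustered networks these models generate are easy instances).

## Synthetic data

The `fixtures` module generates inputs with known expected statistics:
tag populations clustered around well-separated centers (cooperation then
stays within clusters, pinning modularity comparisons) and planted count
matrices — `symmetric` (per-agent r = 1), `antisymmetric` complementary
dyads with given + received constant (per-agent r = −1 for any N; the
3-agent directed ring is the N = 3 case), and i.i.d. `null` matrices
(mean r ≈ 0). These synthetic inputs exercise the statistics exactly; they
do not emulate any empirical data set, and passing tests on them shows the
estimators and engines are correct, not that real animal societies behave
like the model.

## Numerical and design choices

* Continuous coordinates on [0, L) with arbitrary headings (not lattice
  moves): unit displacement is exact to floating tolerance.
* Tag tie-breaking is uniform random, mirroring the stated proximity
  tie rule; with continuous uniform tags exact ties have measure zero but
  the engines handle them exactly (tie keys drawn every step in the
  vectorized path for a fixed RNG call order).
* Selection ranks by fitness with uniform random tie-breaking via a
  random secondary sort key; deterministic tie-breaking would bias by id.
* Degenerate inputs: empty candidate lists, self-directed acts, nonzero
  tallies at generation start, and all-degenerate regression inputs raise
  errors rather than guessing.
* Test problem sizes: property suites that need many replicates run at
  reduced scale (e.g. 100 steps × 20 generations for the selection-vs-
  drift contrast, 200 steps for the trajectory-decline check) — chosen as
  the smallest sizes at which the contrasts are unambiguous; end-to-end
  behavioral checks use the full standard parameterization (N = 50,
  k = 10, 1000 steps).

## Known limitations

* Selection under truncation is rank-based, so only the cost/benefit
  ratio c/b (relative to the variance of received benefits) sets the
  selection intensity against cooperators; cooperators are disfavored for
  any c > 0, including b = c. There is no parameter regime in this model
  in which cooperation is fitness-neutral while still costly.
* The greedy modularity partition is heuristic (guarded by a brute-force
  oracle only at small N), and exact parity with any particular GUI
  tool's community detection is out of scope.
* Replicate-level parallelism, overlapping generations, heritable tags or
  positions, and mutualistic (actor-benefiting) acts are not modeled.
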