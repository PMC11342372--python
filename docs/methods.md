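# Methods

`banditea` implements a dynamic cluster-selection evolutionary algorithm
(EA) for molecular global-minimum searches: a structure library is
partitioned into clusters of structurally similar molecules, and a small
reinforcement-learning agent decides, run by run, which cluster's parent
population the EA should work on next. This note records the models, the
parameters that matter, the numerical choices, and what the desk-scale
experiments do and do not demonstrate.

## Structures and the synthetic library builder

A structure is an ordered list of element symbols with Cartesian
coordinates in Å and an optional total energy in eV. Libraries are built
atom-by-atom: atoms are placed in random order; each non-hydrogen atom is
assigned a hybridization (sp linear, sp² trigonal planar, sp³ tetrahedral;
hydrogen is terminal) that defines its open bonding slots; each new atom
attaches to a randomly chosen open slot at a distance equal to the sum of
the two covalent radii. If any pair of atoms ends up closer than 70% of
the sum of their covalent radii, the whole build restarts. Covalent radii
are single-bond values (C 0.76 Å, H 0.31 Å, N 0.71 Å, …) frozen in
`structures.COVALENT_RADII`. Hybridization weights default to equal
likelihood and are configurable per element. The builder is a simplified
emulation of atom-by-atom library generators — sufficient to produce
diverse, chemically plausible C9H7N-like geometries; it does not enforce
valence completion (an sp³ carbon may end up with fewer than four
neighbours) and performs no bond-order bookkeeping.

Angular placement uses the ideal hybridization angles with a uniformly
random roll about each new bond; no additional angular jitter is applied.
The default study composition is C9H7N (the quinoline stoichiometry).

## Toy energy model

Real energetics (tight-binding or DFT) are abstracted behind a calculator
contract: `evaluate(structure) -> eV` and
`relax(structure, max_steps, force_tol) -> structure`. The packaged
`ToyCalculator` is an all-pairs Morse potential

    E = sum_{i<j} De_ij [ exp(-2a (r_ij - r0_ij)) - 2 exp(-a (r_ij - r0_ij)) ]

with r0 the covalent-radius sum, per-pair well depths De of a few eV
(`structures.MORSE_DE`), and a shared range parameter a = 3.0 Å⁻¹. The
range parameter is the deliberate choice here: at the resulting reduced
range (a·r0 ≈ 4.5) the potential-energy surface is rugged and
multi-funnelled — 40 random builds relax into ~38 distinct minima spanning
~160 eV — which is the regime where a global-optimisation strategy can
actually be distinguished from random sampling. (At a = 2.0 the same
potential has an essentially single compact-blob funnel: every relaxation
reaches the same minimum and all search strategies tie.) Relaxation is
steepest descent with a backtracking line search, so the energy is
monotonically non-increasing; it stops after `max_steps` accepted steps or
when the largest per-atom force norm falls below `force_tol`
(defaults 100 steps, 0.05 eV/Å — the standard capped local-optimisation
rule for EA candidates). The toy model makes no chemical-accuracy claims;
its job is to be deterministic, cheap, analytic, and rugged.

## Fingerprints and distances

Structures are compared without energies via binned radial-distribution
fingerprints. For an element pair (A, B), every A–B distance R contributes
a Gaussian of width δ = 0.2 Å centred at R, integrated over each histogram
bin of width Δ = 0.5 Å on [0, r_max = 8 Å] and weighted by
V_uc / (4π R² N_A N_B Δ); the accumulated histogram is shifted by −1.
Gaussian tails are truncated at ±4δ (< 1e−4 of the mass, deterministic
runtime). Hydrogen is excluded as redundant; by default only the C–C and
C–N fingerprints are used, and the pair list is configurable for other
chemistries. A structure with no nitrogen gets the all-baseline (−1) C–N
fingerprint rather than an error; a structure with none of the configured
pairs is unfingerprintable.

Two same-pair fingerprints are compared with the cosine distance
d = (1 − cos θ)/2, bounded in [0, 1] (a config switch selects the plain
1 − cos θ convention). Per-pair distances combine in quadrature,
√(d_CC² + d_CN²), with equal weighting.

The scaling volume V_uc matters more than it first appears: it scales the
Gaussian sum but not the −1 baseline, so it sets the peak-to-baseline
ratio and with it the numerical scale of all cosine distances. The default
is the volume of the r_max sphere, (4/3)π r_max³ ≈ 2145 Å³ — the natural
molecular stand-in for a crystal's unit-cell volume. With this choice,
distances between distinct small organic molecules land on the
few-times-0.01 scale (median ≈ 0.027 on builder libraries), which is the
scale the default clustering threshold of 0.026 assumes. With V_uc = 1 Å³
all distances collapse to ~1e−6 and no threshold on the documented scale
is meaningful.

## Clustering

Complete-linkage agglomerative clustering on the distance matrix, merging
until the smallest complete-linkage distance exceeds the threshold; every
resulting cluster therefore has diameter ≤ threshold. The implementation
delegates the agglomeration to `scipy.cluster.hierarchy` (`linkage` with
`method="complete"` + `fcluster(criterion="distance")`) and is checked
against a from-scratch O(n³) oracle in the tests. Exactly tied merge
distances are resolved by scipy's internal ordering; ties have measure
zero for the float-valued matrices produced by the fingerprint pipeline.
Cluster ids are renumbered by first occurrence, which makes labelling
deterministic.

Clusters smaller than `min_size` (default 20) are pooled into a single
"misfit" cluster that participates in selection like any other. The
number of clusters is an outcome of the threshold, not a parameter. The
default threshold 0.026 is specific to quinoline-like libraries; the
desk-scale experiments instead take the median of the observed pairwise
distances, which adapts the cutoff to whatever library the builder
produced.

## The cluster-selection agent

Clusters are arms of a multi-armed bandit. Each cluster starts with
selection weight 100; clusters are drawn with probability proportional to
weight, with replacement. After a batch of EA runs reports one run-minimum
energy per selection, four rules parameterised by (A, B, C, D) — defaults
(79, 3, 19, 68), the grid-search optimum for a 9-cluster system — update
the weights:

1. **A** (+) the selection produced an energy strictly below the best seen
   anywhere before the batch *and* that energy is the batch minimum;
2. **B** (+) it produced an energy strictly below its own cluster's
   previous best (stacks with rule 1);
3. **C** (−) rule 2 did not fire;
4. **D** (−) always, scaled by the cluster's share of all selections so
   far (`selections[c] / total_selections`) — an overselected cluster is
   penalised harder.

Design choices, each of which was genuinely open:

* Rule 1 requires both beating the historical best overall *and* being the
  batch minimum (the conjunctive reading of "lowest energy molecule of any
  cluster").
* Rules 1 and 2 stack (+A+B); they are presented as separate conditions
  and the optimum B = 3 is small, so stacking is harmless.
* The rule-4 denominator is total selections across all clusters, making
  the per-cluster ratios comparable within a batch.
* Comparisons use the bests recorded at batch start, and the bests are
  committed after all rules are applied, so the update is order-independent
  within a batch.
* Weights are clamped at a floor of 1 rather than 0, so "prevent negative
  probabilities" also prevents permanent starvation: a penalised cluster
  retains a small revival probability. The floor is configurable
  (`AgentState.weight_floor`). This is consequential: with a floor of 0 a
  cluster whose weight hits the cutoff is never selected again, so
  over-penalised parameter combinations (large D, small A) progressively
  kill clusters at random and can perform far *worse* than uniform
  sampling — a plausible origin of the strict A–D balance reported for
  this class of agent. With the floor at 1 that failure mode is softened:
  badly parameterised agents degrade toward uniform sampling instead of
  collapsing. Exact energy ties do not fire rewards (measure zero under
  continuous energies).

## The Gaussian surrogate and parameter tuning

Tuning (A, B, C, D) against the real EA is far too expensive, so each
cluster's EA output is modelled as a normal distribution fitted to the
run-minimum energies of repeated 50-iteration EA runs from that cluster;
one Gaussian draw then stands in for one EA run. The packaged 9-cluster
reference table (means −558.11 … −555.47 eV, SDs 1.76 … 3.13 eV) ships as
`banditea/data/table1_cluster_models.csv`.

A surrogate trial: a fresh agent; per batch, 5 selections with
replacement, one draw each (each draw representing a 50-iteration run, so
a batch is 250 iterations); the first draw strictly below the success
threshold `e_min` ends the trial, credited at the end of the run in which
it occurred (success on draw j of batch k is iteration k·250 + j·50);
otherwise the agent is updated with the batch's draws; at most 20 batches,
i.e. 5000 iterations. Trials are scored by the cumulative success curve —
the fraction of trials that have succeeded by iteration x — and parameter
combinations by the area under that curve, computed as the per-iteration
step sum on [0, 5000] (maximum 5000). Absolute areas depend on `e_min`;
only orderings between combinations are meaningful.

`e_min` defaults to −560.0 eV for the packaged models. At this value the
per-draw success probabilities are 0.04–0.15, so nearly every trial
succeeds within the first few batches — before the weight updates can
redirect selection — and all parameter combinations score within noise of
one another (measured: the best and worst published parameter rows differ
by ≈ 4 area units out of ≈ 4490 at 4000 trials). The discriminating power
of the agent is instead demonstrated on synthetic models with one cluster
3 SD below the rest, where the tuned parameters lift the area from 958
(uniform) to 1316 and the best cluster's selection share doubles. A
further structural caveat of deep thresholds: below ≈ −562 eV the
highest-SD clusters, not the lowest-mean ones the agent rewards, carry
most of the success probability, so reward-by-minimum partially misaligns
with success there.

The full tuning grid is all integer combinations of A ∈ [0, 80),
B ∈ [0, 40), C ∈ [0, 20), D ∈ [0, 90) — half-open tops, 80·40·20·90 =
5,760,000 combinations. The full grid is supported but cluster-scale;
`default_grid_ranges(stride)` provides the coarse strided version used on
a desk. Reproducibility: trial t of combination i runs on the RNG
substream spawned from (seed, i, t), so grid results are identical for any
worker count or evaluation order.

## The evolutionary algorithm

Parent selection: member i is drawn with probability ∝ F_i·U_i, with the
half-tanh fitness F = ½[1 − tanh(2ρ − 1)], ρ = (E − E_min)/(E_max − E_min)
over the population's energy span (F = 0.5 for all members of a
degenerate population), and the uniqueness factor
U = (1 + n_i)^(−1/2) (1 + m_i)^(−1/2), where n_i counts pairings and m_i
accumulated structural lookalikes. Crossover is cut-and-splice: both
parents are centred on their centres of mass, a uniformly random plane
through the origin keeps one side of each, and the stoichiometry is
repaired — surplus atoms of an element are removed farthest-from-plane
first, deficits are refilled with randomly chosen unused parent atoms. A
child violating the 70% minimum-separation rule is rejected and the splice
retried with a fresh plane (default 50 retries, then the iteration counts
as failed). No mutations are used, isolating the effect of the selection
machinery.

One EA iteration = select two parents, splice, relax the child (≤ 100
steps or force < 0.05 eV/Å), compare: within a fixed-size (swap-only)
population the child replaces the weakest member iff strictly lower in
energy. A child whose combined fingerprint distance to an existing member
is below the similarity threshold (default 0.005) is instead counted as
that member's lookalike (m_i += 1) and discarded.

Between cluster selections the chosen cluster's parent population
(default 20) is re-curated under an energy-spacing rule with threshold
ΔE (default 0.3 eV), scanning candidates in ascending energy:

* **method 1** keeps a molecule iff no other pool molecule lies within
  ±ΔE of it (the full pool is scanned, including molecules already
  excluded); pool = previous run's offspring ∪ previous parents;
* **method 2** keeps the running-lowest molecule whose energy exceeds the
  last kept energy by more than ΔE; same pool;
* **method 3** = method 2's rule over *every* offspring the cluster has
  ever produced ∪ previous parents.

If fewer than `target_size` molecules survive (possible early under
method 3 or for large ΔE), the lowest-energy excluded candidates pad the
list, keeping the population size fixed while violating the spacing rule
as little as possible; the list is then truncated to `target_size`.

The clustered driver initialises per-cluster parents (a fresh seeded
sample per run), then loops: agent selects a cluster → 50-iteration EA run
on its curated parents → agent update with the run minimum → re-curation;
up to 100 selections (5000 iterations), with optional early stop at a
success energy. The unclustered baseline driver seeds one population with
the whole library and appends every relaxed offspring (the population
grows; memory is bounded by the iteration budget).

## Desk-scale experiment conditions

`banditea.experiments` fixes the toy study conditions: a library of 60
random C9H7N builds relaxed under the standard rule; clustering at the
median library distance with undersized clusters (< 6) pooled; clustered
EA with 6 parents per cluster, 20 selections × 10 iterations (200
offspring evaluations), curation method 1 with ΔE = 0.3 eV, parameters
(79, 3, 19, 68). The iteration-matched random-search baseline relaxes 260
fresh builds — exactly the clustered run's total budget (60 library + 200
offspring) — and both sides are credited with every energy they evaluated.
These sizes keep one head-to-head comparison under ~5 s while preserving
the structure of the full protocol (library → clusters → bandit-guided
runs); they are proportionally smaller than the reference protocol
(812-structure library, 100 × 50 iterations, 20 parents), so absolute
energies and success rates are not comparable across scales.

## What the tests show — and what they do not

The property suites (fingerprint invariances, complete-linkage oracle
equivalence, agent floor/zero-parameter fuzzing, curation-rule oracle
equivalence) validate the machinery exactly. The end-to-end comparison
shows that on a rugged toy landscape the clustered, bandit-guided EA finds
lower minima than iteration-matched random search in the large majority of
seeded runs. None of this demonstrates performance on real quantum-level
energetics: the toy potential has no chemistry (no valence, no barriers of
chemical origin), the builder does not reproduce any specific published
library, and the surrogate's packaged models describe EA behaviour under a
tight-binding calculator this package does not ship. The calculator
contract is the integration point for real energetics.

## Known limitations

* The agent's rewards rank clusters by produced minima; when the success
  threshold sits deep below all cluster means, success probability is
  dominated by distribution width and the reward signal partially
  misaligns (see the surrogate section).
* Learning parameters are not normalised for cluster count; (79, 3, 19, 68)
  was tuned for 9 clusters at initial weight 100 and transfers only as a
  starting point.
* Curation method 1's full-pool reading means a molecule can be excluded
  by neighbours that were themselves excluded.
* The unclustered driver's population growth is unbounded by design.
* `relax` guarantees monotone energy descent but only local convergence;
  capped steps intentionally leave unviable candidates unconverged.
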