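# Methods

This note records the models, estimators and numerical choices behind
the package, and what its simulation-based tests do and do not
establish.

## Community model

Communities of N taxa follow generalized Lotka-Volterra (GLV) dynamics,
dx_i/dt = r_i x_i + Σ_j a_ij x_i x_j, with self-regulation fixed at
a_ii = −1 so that each taxon alone settles at its carrying capacity r_i.
Interaction networks are either Erdős–Rényi (each directed off-diagonal
entry present independently with probability ⟨d⟩/(N−1)) or
Barabási–Albert (a complete core of n₀ seed nodes, then
degree-proportional attachment of n₀ edges per new node; each undirected
edge becomes one directed interaction, oriented out of its higher-degree
endpoint with probability d — the *directionality* — and uniformly
otherwise, so hubs preferentially influence their neighbours). Nonzero
interaction values are U(−σ_A, σ_A).

A *sample* is a steady state reached from a random initial assembly:
each taxon present with probability 0.8, initial abundances U(0, 1).
Zero abundance is an invariant manifold of the dynamics, so taxa absent
at assembly stay absent; different assemblies reach alternative stable
states, which is the sole source of presence/absence variation across a
simulated cohort. Samples are column-normalized to relative abundances
for all downstream analysis; the absolute steady states are retained
internally because perturbation experiments must re-integrate from them.

### Parameters that matter

* **σ_A** (interaction scale, per-abundance rate): chosen for ecological
  stability. The package default is σ_A = 0.5/√⟨d⟩ — half the May-style
  stability scale — at which ≥95% of random assemblies converge. When
  every taxon's outgoing interactions are boosted by heavy-tailed
  factors K ~ log-normal(μ=0.5, σ=1), the same argument applies to the
  boosted matrix, and ensembles use σ_A = 0.5/(√⟨d⟩ · E[K]) with
  E[K] = e^{μ+σ²/2}.
* **Growth rates**: U(0, 1) by default (the generic community). For
  designated-keystone demonstration cohorts the package follows the
  unit-growth convention (r_i = 1 for all i): with random growth rates a
  designated keystone can draw r ≈ 0 and be rare and weightless for
  reasons unrelated to its interactions, confounding what the
  demonstration is meant to show.
* **Boost K**: multiplies taxon i's outgoing column a_ji (j ≠ i); the
  diagonal is never boosted, so keystone strength is not conflated with
  the taxon's own carrying capacity. K = 10 creates one designated
  keystone; K ~ log-normal(0.5, 1) creates a realistic spread with a few
  influential taxa.
* **Inoculum** (0.5): the abundance at which an absent taxon is
  introduced in an addition perturbation — the midpoint of the U(0, 1)
  initial-abundance law. In multistable systems the post-addition state
  can depend on it, so it is an explicit, recorded parameter.

## Steady-state integration

The initially-present subsystem is integrated with LSODA (scipy
`odeint`, analytic Jacobian, rtol 1e-8/atol 1e-10) in stages to t = 200
and t = 1000. After each stage the surviving-species fixed point is
*polished*: survivor sets are proposed at increasing extinction cutoffs
(1e-6 … 1e-2), the interior equilibrium x_s = −A_ss⁻¹ r_s is solved
directly, and the solution is accepted only if it is positive, within
5% of the integrated endpoint, and every excluded taxon has a negative
invasion growth rate there (so the trajectory's limit genuinely drops
it). An accepted polish zeroes the derivative exactly, cheaply meeting
the steady-state criterion ‖dx/dt‖∞ / max(‖x‖∞, 1e-12) < 1e-8; without
polish the criterion is checked at each stage. Abundances below 1e-8
are clipped to exact zeros so downstream presence masks are binary;
abundances above 1e6 abort with an instability error carrying the model
seed. Non-converged samples are flagged and excluded from
presence-impact averages (with counts reported), never silently
included.

Perturbed re-integration starts from the prior steady state, not a
fresh assembly: the experiment perturbs *the same community*.

## Estimators

* **Presence-impact** I_k^i: distance between the pre- and
  post-perturbation profiles of all taxa except i, each renormalized to
  1. Excluding the focal taxon removes the arithmetic anticorrelation
  that compositional data otherwise forces. I^i averages valid samples.
* **D1 / D2**: mean cross-pair distance, and distance between group
  means, of the focal-taxon-excluded renormalized profiles, between the
  present and absent sample groups. For singleton groups D1 = D2.
* **Q**: two-group Newman modularity of the thresholded similarity
  network. The threshold T is the empirical p_Q-quantile (linear
  interpolation) of all pair distances, ties at T admitted, so the edge
  count may slightly exceed the nominal fraction — a deterministic rule
  in preference to random tie-breaking. The modularity sum runs over
  all ordered node pairs including the diagonal null-model term (there
  are no self-edges, b_αα = 0); this convention is what pins Q = 0 for
  uniform labels, Q = 0.5 for two disconnected equal cliques labeled by
  component, and Q ∈ [−0.5, 1] generally. Isolated nodes are retained
  and contribute only the null term. An edgeless network has undefined
  Q, reported as missing with a warning.
* **Candidate rules**: the keystone flag is value > mean + 2·SD
  (sample SD, statistics over all eligible taxa, focal taxon included);
  the z-test excludes the focal taxon from its background mean/SD and
  reports a one-tailed normal p. Under normality the 2-SD rule flags
  ≈2.3% of taxa — the baseline against which observed candidate rates
  are judged.
* **Frequency window**: real-survey screens restrict to taxa present in
  25–75% of samples (inclusive; the boundary convention is ours, the
  window endpoints are standard). A taxon present in all or no samples
  has no presence contrast and its EPI is undefined; near the extremes
  the minority group is small and D1/D2 are biased upward. Simulated
  demonstration screens use the full window, since simulated frequencies
  concentrate near the assembly probability.
* **Longitudinal EPI** L^i: within-subject distance of the
  focal-excluded renormalized profiles, averaged over subjects whose
  presence state for taxon i reversed between collections; taxa with 10
  or fewer reversal subjects (i.e. eligibility requires ≥ 11) are
  reported but marked ineligible. Agreement with a cross-sectional EPI
  is summarized by Pearson correlation on the common eligible taxa and
  by the overlap of the top-5% candidate sets, tested with a one-sided
  (enrichment) Fisher exact test; candidate sets use strict ranking
  with a stable tie-break by taxon order.
* **Co-occurrence network**: pairwise NMI between binary presence
  vectors, normalized by the arithmetic mean of the marginal entropies
  (geometric-mean normalization available behind a flag); constant
  vectors carry no information and score 0. Edges keep the top quartile
  of NMI values (quantile with ties admitted) and are signed by the
  Pearson correlation of the presence vectors — the network is
  presence-based throughout, so its edge signs are too. The
  neighbor-EPI statistic is the Pearson correlation over the
  symmetrized edge list, with a node-label permutation null and the
  add-one permutation p-value. `find_modules` (greedy modularity
  communities on the positive-sign subgraph) is exploratory convenience
  only; systematic keystone-module identification is an open problem.

## Null models

The fixed-margin presence shuffle performs checkerboard (2×2 submatrix)
swaps, preserving every taxon's frequency and every sample's richness
exactly. The default swap budget is 10× the number of ones; swaps are
proposed by rejection sampling, and a matrix admitting no checkerboard
is returned unchanged with a warning. All shuffles and permutation
tests are deterministic given their integer seed.

## What the simulations do and do not show

The generator emulates the presence/absence structure and
compositionality of survey data via multistable GLV assembly. It does
not emulate sequencing noise, sampling depth, taxon-abundance
heavy tails, host covariates, or temporal autocorrelation between
paired collections (the second collection is an independent
re-assembly of the same community). Passing tests therefore establish
that the estimators recover engineered dynamical influence under ideal
sampling — not that they are robust to measurement error in real
surveys, where the frequency window and detection-threshold parameters
exist to absorb part of that gap.

Test and demonstration problem sizes are chosen at desk scale: N = 50,
M = 50 with 20 replicate seeds for keystone recovery; N = 50, M = 100
with three pooled replicates for the EPI-impact correlation (dense
networks, ⟨d⟩ = N/2, where cross-sectional footprints are strongest);
N = 100, ⟨d⟩ = 50, H = 80 subjects for the paired-cohort shuffle
analysis. One caveat from these sizes is worth stating: on sparse
networks (⟨d⟩ = 10) a designated keystone reliably tops the
perturbation-impact ranking, but its *cross-sectional* footprint is
weak relative to assembly variability, and the three EPI measures
flag it jointly in only a minority of replicates; dense interaction
networks are where the cross-sectional measures earn their keep. At
desk scale the label-shuffle null also retains a residual EPI-vs-L
correlation through a label-free pathway — dropping a high-impact
taxon's row leaves a genuinely bimodal dataset, elevating both its
shuffled D1 and its shuffled L — which shrinks as N grows and is why
the shuffle analysis is run at N = 100.
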