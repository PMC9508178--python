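# Methods

## Problem

Modularity maximization is the most widely used family of community-detection
methods, but in practice it confronts the user with three coupled difficulties:
a resolution parameter γ (and, for multilayer networks, an interlayer coupling
ω) must be chosen; the popular optimization heuristics (Louvain, Leiden,
spin-glass) are stochastic and return different near-optimal partitions on
repeated runs; and different parameter values yield genuinely different
partitions.  This package implements a pruning framework that turns an
arbitrary pool of candidate partitions into a small set of *stable* partitions
that are self-consistent under an equivalence between modularity and inference
of a degree-corrected planted-partition stochastic block model (SBM).

## Model and procedure

**Quality functions.**  Single-layer modularity at resolution γ is

    Q(γ) = (1/2m) Σ_ij [A_ij − γ k_i k_j / 2m] δ(g_i, g_j),

summed over ordered node pairs including i = j; a self-loop of weight w
contributes A_ii = 2w so that k_i = Σ_j A_ij and 2m = Σ_i k_i hold exactly.
Multilayer modularity adds uniform interlayer couplings of weight ω between a
node and itself in coupled layers (temporal chain or multiplex all-pairs) and
normalizes by 2μ = Σ_is (k_i^s + Σ_r C_i^{sr}).  The interlayer sum runs over
*ordered* layer pairs, so each physical coupling enters the numerator and 2μ
twice; every downstream convention (the coupling count Ĉ, the ω estimate's
denominator) is calibrated to this choice.

**Linear decomposition.**  For a fixed partition both quality functions are
affine in the parameters: Q̃(γ, ω) = Â − γP̂ + ωĈ, where Â is the
within-community adjacency weight, P̂ the within-community null-model mass, and
Ĉ the matching interlayer-coupling count.  Since the normalization 2μ(ω) is
partition-independent at fixed parameters, comparing Q̃ across partitions is
equivalent to comparing modularity.

**Domains of optimality.**  Over any pool of partitions, the pointwise maximum
of the Q̃ lines (1-D) or planes (2-D) is an upper envelope; each partition's
domain of optimality is convex — an interval in γ or a convex polygon in
(γ, ω).  Partitions with a non-empty domain in the queried range form the
*admissible* subset.  The 1-D envelope is computed by a sorted-slope stack
sweep; the 2-D envelope prunes the pool to the upper convex hull of the dual
points (−P̂, Ĉ, Â) (Qhull) and clips the query rectangle by the pairwise
dominance half-planes of the surviving planes.

**Parameter estimates.**  Modularity maximization at γ is equivalent to
maximum-likelihood fitting of a degree-corrected planted-partition SBM with
within/between propensities θ_in, θ_out when γ equals their logarithmic mean
(θ_in − θ_out)/(ln θ_in − ln θ_out).  Given a partition, the propensities are
estimated as θ_in = 2m_in/(Σ_c κ_c²/2m) and
θ_out = (2m − 2m_in)/(2m − Σ_c κ_c²/2m), with κ_c the community degree sum.
For multilayer partitions the sums are accumulated per layer before the
ratios are taken (ratio of sums, chosen for degree-sum consistency; a mean of
per-layer ratios is the natural alternative and would differ only for strongly
heterogeneous layers).  The temporal model supplies a second relation,

    ω = ln(1 + pK/(1−p)) / (2 (ln θ_in − ln θ_out)),

where p is the probability that a node's label is *copied* from the previous
layer and the factor 2 reflects the ordered-pair interlayer convention above
(one documented constant, `INTERLAYER_DOUBLING`, holds it).  The persistence
frequency f of labels across consecutive layers overstates copying, because a
resampled label still agrees with probability 1/K; the copying probability is
therefore recovered by the chance correction p = (f − 1/K)/(1 − 1/K) before
entering the ω formula.  With K = 2 and copying probability η this gives the
regime anchors ω ≈ 0.95 (η = 0.7, ε = 0.4) and ω ≈ 0.79 (η = 0.5, ε = 0.5)
that the tests check against.  Degenerate inputs have explicit contracts: the
single-community partition has no estimate; a zero propensity yields no γ
estimate; identical labels in every layer yield ω = +∞.

**The finite-state map.**  Each admissible partition is sent to the admissible
partition that is optimal at its estimated parameter point.  Locating the
containing domain reduces to an argmax of Q̃ over the admissible coefficients
at that point, which also resolves boundary points by maximum quality
(remaining exact ties go to the lower state id — estimates do land near domain
boundaries in practice).  Because the state space is finite the map is
deterministic given the pool, and every state reaches a fixed point, a
periodic orbit, or an escaped state (undefined or out-of-range estimate) in at
most |states| steps.  Fixed points — partitions whose estimates fall inside
their own domains — are the stable partitions.  Orbits are detected and
reported rather than assumed absent, since their impossibility for assortative
partitions is conjectural.  An infinite ω estimate is clamped to the top of
the analysis ω range by default (`clamp_infinite_omega`), mirroring how such
partitions are conventionally visualized; with clamping off they escape.

**Resolution bound.**  For an assortative planted partition of K equal blocks
the propensities satisfy 0 ≤ θ_out ≤ 1 ≤ θ_in ≤ K (mean propensity one,
within-block mass at most K).  The logarithmic mean is increasing in both
arguments, so the γ estimate is bounded by γ_max(K) = (K−1)/ln K, attained at
(θ_in, θ_out) = (K, 1).  The closed form is derived here from that feasible
region; a constrained numerical maximization is exposed as an independent
check and agrees to 1e-6 for K = 2..50.  `bound_check` verifies estimates
against the bound, skipping disassortative fits, and is useful for choosing
sweep ranges a priori.

## Synthetic models

* **Hierarchical blocks**: 450 nodes, 9 equal blocks grouped into 3
  communities of 3 subcommunities; independent edges with probability 0.12
  within a subcommunity, 0.03 within a community across subcommunities, and
  1/600 between communities.  Both the 3- and the 9-community descriptions are
  planted truths; the pruning map recovers both (and often an intermediate
  6-community substructure) as simultaneously stable partitions.
* **Temporal label copying**: first-layer labels split evenly among K;
  each subsequent layer copies a node's label with probability η and otherwise
  resamples uniformly (consecutive agreement η + (1−η)/K).  Intralayer edges
  are Bernoulli with p_in inside and p_out = ε·p_in between communities;
  layers form a temporal chain.  The regime parameters studied are
  (η, ε) = (0.7, 0.4) ("easy") and (0.5, 0.5) ("hard") with T = 15, K = 2,
  150 nodes per layer.  p_in is not pinned by the regime definition (the
  estimates depend on the edge probabilities only through ε); the default sets
  p_in for a mean degree of 20 at the canonical sizes, a typical density for
  these benchmarks, and is configurable.
* **Equal blocks**: single-layer planted partition with K equal blocks, the
  workhorse fixture; for K = 2 the expected γ estimate of the planted labels
  has the closed form 2(1−ε)/((1+ε) ln(1/ε)) used as an oracle.

Labels are always drawn before edges from one seeded generator, so the label
stream is unchanged when only edge probabilities vary, and identical seeds
reproduce networks exactly.  What these generators do *not* emulate: degree
heterogeneity within blocks, weighted or directed edges, layer-dependent
densities, and node sets that differ between layers.  Passing tests therefore
certify the machinery on networks that match the SBM's assumptions; on real
data the equivalence is only known for unweighted multigraphs, and weighted
input triggers a warning in the estimators.

## Heuristic backends

Input pools are produced by pluggable maximizers: Leiden (leidenalg) is the
default, with multilayer optimization done on the supra formulation (one
per-layer configuration-null partition per layer plus an ω-weighted coupling
partition, optimized jointly); igraph's spin-glass heuristic serves fixed-K
single-layer searches; a brute-force enumerator (≤ 13 items) is the exact
oracle; and a greedy agglomerator is a dependency-free fallback.  Fixed-K
requests on backends without native support are met by rejection-filtering
unconstrained runs, which fails loudly when the heuristic never visits that K.

## Numerical choices

* Envelope/crossing tolerance 1e-10 (relative); domains thinner than this are
  dropped as slivers.  Exact duplicate coefficient vectors collapse to the
  earliest representative, with the duplicate ids retained.
* Map ties: argmax of Q̃ with relative tolerance 1e-10, then lowest state id.
* Iterative procedures stop on parameter change (|Δγ|, |Δω| < 1e-3 by
  default, 25 iterations maximum); partitions may alternate while parameters
  converge.  Oscillation and divergence are reported in the trace, never
  forced to converge; this is exactly the behavior that distinguishes the
  hard temporal regime.
* Multiplex copying probability is defined as mean label agreement over all
  coupled layer pairs — an extension of the temporal definition, flagged with
  a warning at call time.

## Study sizes used by the tests and the acceptance script

Chosen once as the package's canonical experiment sizes: the karate club
sweep uses 10⁵ Leiden maximizations on a 500-point γ grid over [0, 2]
(results stabilize far below this); the hierarchical experiment uses 100
realizations with 500 maximizations each on a 100-point γ grid over [0, 2.5];
the temporal pipeline uses a 30×30 (γ, ω) grid over [0, 2]² with one run per
point; planted-label estimates are averaged over 5 seeded realizations since
a single hard-regime realization's ω estimate fluctuates by roughly ±0.05.

## Known limitations

* The SBM equivalence — and hence every estimate — is only known for
  unweighted multigraphs; weighted quality evaluation is supported, weighted
  estimation is use-at-own-risk (warned).
* Parameter spaces are limited to one or two dimensions (γ or (γ, ω) with
  uniform per-layer resolution and uniform coupling weight).
* Node identity across layers is positional; differing node sets per layer,
  directed intralayer null models, and multilevel topologies are out of scope.
* The pruning can only ever return partitions present in the input pool: if
  the heuristics never find a good partition, no post-processing will.
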