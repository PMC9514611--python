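# Methods

## Model class

A model is a set of demes with relative effective sizes `Ne_d/Ne_ref`,
per-deme unphased or phased sample counts, unidirectional continuous
migration routes, and at most one discrete event: a mass migration that
moves all lineages of one or more source demes into a destination deme at a
fixed time `T`, which, with several sources and an initially empty
destination, realizes a population split viewed backwards in time.  All
rates and times are in coalescent units of `2·Ne_ref` generations: the
pairwise coalescence rate in deme `d` is `Ne_ref/Ne_d`, a per-generation
backwards migration fraction `m` becomes a per-lineage rate `2·Ne_ref·m`,
and an absolute time `t` generations becomes `t/(2·Ne_ref)`.

Migration routes must not form a directed cycle: cyclic state spaces (e.g.
bi-directional migration) make the transition graph cyclic and are rejected
at model construction.  Models whose event can become a no-op (all source
demes empty) and later re-arm — possible only if a migration route feeds a
source deme that had emptied — are rejected at collapse time; no standard
isolation-with-migration layout has this shape.

## Branch types

Lineages are labelled by the samples they subtend.  Unphased samples are
labelled by their deme of origin, so a lineage reduces to a per-deme count
vector; phased samples keep unique labels.  A rooted, phased sample of size
`n` distinguishes `2^n - 2` branch types; discarding root information folds
each type with its complement relative to the full sample.  The canonical
order is lexicographic on the count vector (unphased) or on the sorted
label tuple (phased), with the lexicographically smaller member of each
complement pair as the folded representative.  This order is deterministic
and is printed in every output header; no canonical order is inherent to
the problem, so any consumer should read the header rather than assume one.

## The state graph and its equations

States `Ω` (per-deme multisets of lineages, plus a fired/not-fired flag for
the discrete event) are generated breadth-first from the sampling
configuration.  Grouped transitions carry integer coefficient vectors
`(p, q)` over the global rate vector `r = (λ, δ, ω)`: `q` counts every
competing event's multiplicity from the parent state plus the number `o_k`
of extant branches of each type; `p` is one-hot on the realized event with
its multiplicity.  The per-edge transform is `(p·r)/(q·r)`; identical
outcomes are merged with multiplicity folded into `p`; equations are
deduplicated into a global table.  Any state with a single remaining
lineage is absorbing.  The mass migration is emitted from every state where
it would change the state; where its sources are already empty it is a
no-op and neither the edge nor the `δ` competition is recorded — for the
supported model class the two formulations are equivalent (the geometric
sum over no-op firings telescopes away).

## Evaluation as a computational graph

For models without a discrete event the computational graph is the edge
dual of the state graph: one node per edge, children = continuations, and
the transform is obtained by summing children before multiplying with the
parent's value, once per node, in topological order.  With a discrete
event, each path's prefix up to and including the `δ`-involved edges is
collapsed into a single node whose value is the closed-form inverse Laplace
transform in `δ`:

    L^-1[ Π_i 1/(c_i + δ) ](T) = Σ_i e^{-c_i T} Π_{j≠i} 1/(c_j - c_i).

The formula is implemented by residue calculus (the sign convention above
was fixed against a high-precision numerical inversion oracle rather than
taken on faith).  Prefixes on which the event never fires (the mrca
predates `T`) keep the global `1/δ` factor as an extra pole at `c = 0`;
this is the unique convention under which the inverted transform equals 1
at `ω = 0` for every `T`.  Poles closer than a relative `1e-9` are treated
as confluent: the residue is computed from a short univariate expansion
around the clustered pole, which covers arbitrary multiplicities without
the unstable distinct-pole formula.

The printed structural "node counts" of the method refer to this
computational graph: for migration-only models it equals the state-graph
edge count; with a discrete event each distinct collapsed prefix is its own
node, which is why discrete events disproportionately grow the graph.

## Taylor propagation and the bSFS

The probability of mutation configuration `k` is
`P(k) = (-θ/2)^{Σk} · c_k`, with `c_k` the Taylor coefficient of the
(inverted) transform at expansion point `ω = θ/2` per branch type; this
follows from writing the Poisson mixture
`E[Π_i e^{-(θ/2)L_i} ((θ/2)L_i)^{k_i}/k_i!]` in terms of `∂^k E[e^{-ω·L}]`.
Each node's factor has closed-form coefficients: for first-degree
`f(ω) = b + Σ c_i ω_i`,

    coeff_k[f^{-t}] = (-1)^s (s+t-1)!/((t-1)! Π k_i!) · Π c_i^{k_i} · f(ω0)^{-(s+t)}
    coeff_k[e^{c f}] = c^s Π c_i^{k_i} e^{c f(ω0)} / Π k_i!

with `s = Σ k_i` (both validated against symbolic differentiation).
Collapsed nodes combine these per pole; pole polynomials that are equal as
polynomials use the confluent expansion, while distinct polynomials whose
values happen to collide at `ω0` (a removable singularity) are resolved by
averaging a symmetric `±ε` perturbation, cancelling the leading error term.
Coefficients (derivatives over `Π k_i!`) are stored rather than raw
derivatives, keeping magnitudes down by `(Σk)!`.  Tables are propagated
with the same graph sweep; addition is elementwise, multiplication is
truncated multi-index convolution, and every reduction with mixed signs
uses compensated (two-sum/Neumaier) accumulation, which keeps sums accurate
to a few ulp under heavy cancellation.

Residual bins (`k_i > kmax_i` for a set `S` of types, exact counts
elsewhere) are computed by inclusion–exclusion over marginal arrays
obtained by re-propagating with `ω_i = 0` for `i ∈ S'` (removing the
marking process on those types), for each subset `S' ⊆ S`.  For `|S| = 1`
this reduces to "marginal minus the within-bound sum"; for larger `S` the
inclusion–exclusion is required so that a joint residual cell means *all*
listed types exceed their bound, matching the per-type Poisson-tail
convention of the Monte-Carlo estimator.  The full array then sums to one
by construction; the tests require `1e-8`.

## Structural zeros

A configuration has non-zero probability iff the branch types it marks
co-occur along at least one root-to-absorption path — equivalently, appear
together in the clade set of at least one realizable genealogy.  Path
supports are computed by dynamic programming over the DAG (no path
enumeration), closed downward, and stored as bitmask sets; compatibility is
monotone under support shrinkage by construction.  Incompatible cells are
exact zeros in the output and are never computed.  The Monte-Carlo
cross-check (every simulated support must be flagged compatible) guards
against false zeros.

## Monte-Carlo oracle

The simulator draws structured-coalescent genealogies directly under the
same event semantics (competing exponentials; the split applied
deterministically at `T`; post-split migration through the vanished demes
disabled) and accumulates per-branch-type lengths.  Mutation-configuration
probabilities are estimated as the replicate average of products of Poisson
probabilities with rate `θ/2` per unit branch length (tail mass into the
residual bins); each replicate's table sums to one exactly, so the
estimate does as well.  Replicate `r` draws from a stream seeded by
`(seed, r)`, so increasing the replicate count never reshuffles earlier
draws.  The default validation uses 1000 replicates, which resolves the
`4^4` benchmark array entries to a few times `1e-4`; agreement within four
standard errors on every compatible entry is the acceptance requirement.

What the simulator emulates — and what passing tests therefore show — is
the model class itself: exponential waiting times, one discrete event,
infinite-sites marking.  It shares no code path with the exact engine
(direct stochastic simulation versus transform algebra), but it does not
probe model misspecification against real data: no recombination within
blocks, no sequencing error, no mutation-rate heterogeneity.

## Numerical choices

- Double precision throughout; no arbitrary-precision arithmetic in the
  production path.  Compensated summation bounds cancellation error in the
  series convolutions and pole sums.
- Pole-confluence tolerance `1e-9` (relative); perturbation size for
  removable value collisions `1e-6·scale`, with symmetric averaging giving
  an `O(ε²) = 1e-12` residual error.
- Tiny negative probabilities from cancellation (|x| < 1e-12) are clipped
  to zero; anything larger is a genuine failure and is not masked.
- Dense configuration arrays are used up to `1e7` slots; the 4-per-deme
  array (`4^12` slots) is handled through its layout (counts, iteration
  over compatible cells) without dense materialization.

## Problem sizes

The bundled tests and validation scripts run the migration-only model at
2–4 samples per population (graphs of 30/196/1106 computational nodes) and
the IM model at 2–3 (76/4449 nodes); full bSFS tables with residual bins
are computed for up to seven branch types (`4^7` entries).  These sizes
exercise every code path — folding, collapse, confluent poles, residual
bins — while keeping the whole suite under a minute of compute; the
algorithms themselves scale to whatever memory allows, with the
configuration-array size `Π(kmax_i+2)` as the binding constraint.

## Known limitations

- One discrete event per model; no bottlenecks or stepwise size changes.
- No cyclic migration (see above) and no recombination across blocks.
- The residual-bin computation re-propagates once per subset of residual
  types actually needed; for many branch types with large `kmax` this is
  the dominant cost.
- Phased mode is exact but the state space grows with labelled samples;
  it is intended for small `n` (≤ 6), where the equiprobable-class
  machinery recovers most of the savings.
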