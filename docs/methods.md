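# Methods

## Model

A signed influence graph G(V, E) has directed edges (s, t, σ, w) with sign
σ ∈ {+1, −1} and weight w > 0.  A coloring assigns every node a state shift
`up` or `down`.  An edge *explains* its target when the target's color equals
(activation) or opposes (inhibition) the source's color.  For a total coloring
c the objective is the lexicographic triple

F(c) = ( |{t : no incoming edge explains t}|,
         |{t : some incoming edge fails to explain t}|,
         Σ over failing edges of w ).

The solution concept is the complete set of colorings minimizing F — not a
single witness.  Because the explanation rule is symmetric under swapping
`up`/`down` everywhere, F is invariant under a global flip, and the optimal
set without node fixing is flip-closed; every component derived later
therefore has exactly two mutually-reversed configurations.

Nodes with no predecessors are unconstrained; nodes with no incident edges at
all are free variables that double the model count, which is why they are
excluded from enumeration (the "core" graph) and re-attached afterwards as
color-independent singleton components.

Self-loops are rejected before coloring: the explanation rule does not define
self-regulation semantics, and failing loudly was preferred over inventing
them.  The parser accepts them so that files can still be inspected.

## Enumeration backends

* `bruteforce` — vectorized scan of all 2^n colorings (numpy, bit-indexed),
  refused above a configurable cap (default 20 nodes, i.e. ≤ 1M colorings;
  after reduction this covers moderate networks).
* `branchbound` — depth-first search assigning nodes in sorted order; a
  target's contribution is added as soon as it and all its predecessors are
  assigned.  Since contributions are nonnegative and lexicographic order is
  monotone under coordinatewise growth, a partial score strictly greater than
  the incumbent can be pruned; ties are kept, so the backend collects the
  complete optimal set.  Both backends are verified to return identical sets
  on a 200-graph random corpus.
* `asp` — emits the equivalent logic program (facts `edge/4`, a 1-of-2 choice
  rule per node, consistency/imperfection rules, three `#minimize` statements
  at priorities 3 > 2 > 1) and solves it with clingo when installed; without
  clingo the backend raises, never silently falls back.  The emitted text is
  also available separately (`emit_asp_program`) for use with an external
  grounder.

Weights are exact `fractions.Fraction` values; before enumeration all weights
are rescaled by their common denominator so every arithmetic comparison is on
integers — two colorings never tie or separate through floating-point noise.

## Graph reductions and their exactness

The three rewrites run successively — consistency to fixpoint, co-regulators
to fixpoint, edge balance — because a co-regulator merge creates, on its own
successor, a fresh single-incoming-edge pattern; folding that in would be
sound but collapses structure the successive order keeps (the bundled toy
network's five connected subcomponents would become four).  An option
re-enters the sequence after a balance pass that deleted edges.

Each rewrite must preserve the *complete* optimal model set, not merely the
optimal objective.  Two guards, beyond the textbook patterns, are needed for
that to hold on arbitrary graphs:

* **Cycle guard (consistency merge).**  Merging a single-incoming target t
  with its predecessor forces the edge to be satisfied.  If t lies on a
  directed cycle whose conflicts are unavoidable, that edge may be the
  cheapest one to sacrifice: for p→t (+, w=1), t→q (+, w=5), q⊣p (w=5) the
  true optimum is (1, 1, 1) — violate the cheap edge — while the merged graph
  forces (1, 1, 5).  The merge is therefore applied only when neither
  endpoint lies in a non-trivial strongly connected component of the current
  reduced graph.  On acyclic graphs (where a fully consistent coloring always
  exists and every optimal coloring satisfies every single-incoming edge) the
  guard never triggers.
* **Single-sign guard (co-regulator merge).**  A predecessor-free node whose
  edges to the shared successor form a balanced +/− pair has a genuinely free
  color (one of the pair fails whatever happens); merging it with a true
  co-regulator would drop half the optimal models.  A co-regulator candidate
  must have exactly one, single-signed, edge to the successor; balanced pairs
  are handled by the edge-balance rule instead.
* A flagged (permanently imperfect) target is never consistency-merged: the
  pattern's premise — the single edge is satisfied in the models of
  interest — does not hold for it, and at weight priority the edge can be
  worth sacrificing.

Edge balance subtracts min(w1, w2) from an opposite-signed pair between an
ordered subcomponent pair.  Because the source subcomponent has one color,
exactly one of the two edges explains the target in every coloring: the
target is permanently consistent, permanently imperfect, and contributes
exactly min(w1, w2) regardless of colors.  That constant is stored as a
per-target flag (`always_consistent_imperfect`, `residual_weight`) and added
back during evaluation, so original and reduced graphs report identical
objective vectors.  A flagged subcomponent that loses all incident edges
becomes an isolated, color-independent component whose residual still enters
the objective as a constant.

Soundness — expanded reduced-graph optima equal full-graph optima, with
identical objectives — is asserted exactly (set equality) over the random
corpus in the test suite, for both the default and the re-entrant order.

## Components, similarity, validation

Correlation is computed over the complete model set (never a sample): for
each unordered pair, a = #models colored alike, b = #models colored opposite;
positive ⇔ b = 0, negative ⇔ a = 0, independent otherwise.  Positive/negative
correlation over the complete set is transitive; membership and relative
signs are maintained with a parity union-find, and a sign contradiction along
two closure paths — impossible if the model set is exact — is asserted.  The
canonical configuration C¹ assigns `up` to the lexicographically smallest
member; this is a reporting convention only, since MS is invariant under
swapping C¹/C².

Discretization: `up` if value ≥ fold·mean, `down` if value ≤ mean/fold
(fold default 1.2, raw scale; boundaries inclusive so the discretizer is
monotone in the value; a log2 mode exists but is off by default).  Genes with
nonpositive control means are skipped and counted.  Observations attach to
graph nodes by exact identifier match; any node appearing in a profile is
treated as observable.

MS = max(k, n−k)/n over the n observed member nodes (k = agreements with C¹);
undefined and flagged when n = 0.  Validation: per profile, `n_random`
(default 5) sign-shuffled copies conserving the up/down counts; Welch's
t-test (scipy, Welch–Satterthwaite df) compares real MS values against the
pooled shuffled MS values, and case vs control MS for specificity.  The 0.05
threshold is a reporting default, not logic.  All randomness flows from one
root seed through `numpy.random.default_rng`.

## Synthetic data

`random_signed_graph(n, m, p_inhibition, weight_range, seed)` draws a simple
directed graph without self-loops, edges uniform over ordered pairs, signs
Bernoulli, integer weights uniform in range — the property-test corpus uses
5–12 nodes, densities 1.2–2×n, inhibition rates 0.2–0.8 and weights 1–3,
sizes at which exhaustive 2^n enumeration is feasible as the oracle.

`synthetic_profiles` draws observation sets from a chosen component
configuration: each member observed with probability 1 − unobserved_rate,
each observed sign flipped independently with probability ε < 1/2.  Noise is
a discrete sign flip, matching the discrete observation model, not Gaussian
expression noise.  Expected MS for an m-node component is
E[max(B, m−B)]/m with B ~ Binomial(m, 1−ε), ≈ 1−ε for ε well below 1/2; the
recovery tests use ε = 0.1 on a 100-node component with 200 samples and a
3-standard-error band.  The generator does not emulate gene–gene correlation
structure, batch effects, or the mapping from probes to network nodes of real
expression data, so passing recovery tests demonstrate statistical behavior
of the MS machinery, not biological fidelity.

The bundled toy network (9 nodes, 11 edges, unit weights) is a reconstruction
constrained by its documented behaviors — the three reduction outcomes, the
two optimal colorings, the two components and the MS = 2/3 worked value — and
the tests assert those behaviors.

## Problem sizes and numerical choices

The default suite and the acceptance script run in seconds on one CPU: the
oracle corpora use ≤ 12-node graphs (4096 colorings, vectorized), the
calibration study 1000 repetitions of a 16-profile, 40-node-component null,
chosen as the smallest sizes at which the binomial/uniformity bands are
informative.  Exact rational weights remove tie-breaking concerns entirely;
serialization orders nodes lexicographically for reproducible files; reruns
with the same seed produce byte-identical summaries.

## Known limitations

* Enumeration is exhaustive by design; graphs whose *reduced* core exceeds
  ~20 nodes need the branch-and-bound backend or an external ASP solver, and
  very large solution sets (the set itself can be exponential) are inherently
  expensive to materialize.
* The cycle guard makes the consistency reduction conservative on feedback
  structures: nodes inside strongly connected components are never merged,
  so densely cyclic graphs reduce less than the textbook pattern would
  suggest.
* Component identification requires the complete model set; a sampling mode
  would classify some pairs "independent" spuriously and is deliberately not
  offered.
* Enrichment (SE/CQ) consumes externally computed enrichment tables and an
  ontology snapshot; no ontology version is bundled and no enrichment test is
  performed.
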