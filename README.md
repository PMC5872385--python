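# perfcolor

Perfect-coloring analysis of signed regulatory networks: enumerate the
qualitative network states that best agree with the wiring of a signaling /
regulatory graph, decompose the graph into color-correlated components, and
score those components against discretized gene-expression profiles.

## The problem and the model

Pathway databases describe regulation as a signed directed graph: nodes are
molecular species (genes, proteins, complexes, reaction events) and each edge
carries an activation (+1) or inhibition (−1) sign and a positive weight.  A
*coloring* assigns every node a qualitative shift `up` or `down` — the change
one would measure between two cellular conditions.  A target node (one with at
least one predecessor) is

* **consistent** when at least one incoming edge *explains* its color
  (activation copies the predecessor's sign, inhibition flips it), and
* **imperfect** when at least one incoming edge fails to explain it; each
  failing predecessor is an *imperfect regulator* contributing its edge weight.

A **perfect coloring** is a coloring attaining the lexicographic minimum of

```
( #inconsistent targets , #imperfect targets , Σ weight of imperfect regulators )
```

The package enumerates the *complete* set of optimal colorings (the rules are
sign-symmetric, so the set is closed under a global flip).  Because the naive
space is 2^n, three behavior-preserving graph reductions are applied first:

1. **consistency** — a target with a single incoming edge merges with its
   unique predecessor (relative sign = edge sign);
2. **co-regulators** — two predecessor-free nodes sharing the same unique
   successor merge (relative sign = product of their edge signs);
3. **edge balance** — same-sign parallel weights between two subcomponents are
   summed, opposite-sign pairs `(w1, w2)` become `(w1−min, w2−min)`, zero
   edges are deleted; a target losing a balanced pair is permanently
   consistent-and-imperfect and remembers the cancelled weight, so the
   reduced graph reproduces the original optimum *exactly*.

Across all optimal colorings, two nodes are positively / negatively correlated
or independent; the transitive closure of the correlated pairs partitions the
network into **components**, each with exactly two mutually-reversed
configurations C¹ and C².  An expression profile, discretized against control
means with a 1.2-fold threshold (`up` if value ≥ 1.2·mean, `down` if
≤ mean/1.2), is compared to a component by the **maximal similarity**

```
MS = max(|obs ∩ C¹|, |obs ∩ C²|) / |obs|          (MS ∈ [1/2, 1])
```

and each component is validated by Welch's t-test of real MS values against
MS values of sign-shuffled profiles (5 randomized datasets per profile), plus
a case/control specificity test.  SE/CQ metrics for comparing the component
partition with other clusterings of the same network are also provided.

## Worked example

The package ships a 9-node, 11-edge toy network (`perfcolor.toy_graph()`).

```sh
$ perfcolor reduce toy.tsv -o reduced.tsv
reduced to 6 subcomponents (1 isolated), 6 edges
```

The reductions merge {D,E,F} (consistency), {B,C} (co-regulators), and cancel
the balanced I→G edge pair, isolating I and flagging G.  Coloring the reduced
graph:

```sh
$ perfcolor color toy.tsv
# objective: inconsistent=0 imperfect=1 weight=1
A       B       D       G       H
down    down    down    up      up
up      up      up      down    down
```

Exactly two mutually-reversed optimal colorings, with no inconsistent target
and a single imperfect target (G, through the cancelled balanced pair).
Correlating them yields two components:

```sh
$ perfcolor components toy.tsv
#component      member  relative_sign
C1      A       +1
C1      B       +1
...
C1      G       -1
C1      H       -1
C2      I       +1
```

Scoring the observation set `{D: up, E: up, G: up}` against C1, whose
configuration C¹ colors A–F `up` and G,H `down`: D and E agree with C¹
(Sim_C¹ = 2), G agrees with C² (Sim_C² = 1), so MS = max(2,1)/3 = 2/3:

```sh
$ perfcolor score toy.tsv obs.tsv
#component      sample  n_observed      sim_c1  sim_c2  ms
C1      obs     3       2       1       2/3
C2      obs     0       0       0       NA
```

The same workflow is available as a library (`reduce_all`,
`enumerate_optimal`, `identify_components`, `maximal_similarity`,
`validate_components`) and as one call, `run_pipeline(RunConfig(...))`, which
writes model, component, MS and validation tables plus a JSON summary.

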