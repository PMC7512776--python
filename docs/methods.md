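# Methods

## Model

The centrality treats a node's power as the sum of what it exerts on its
immediate neighborhood and what leaks two hops out.

**Ego subgraph.** For node *i*, Gᵢ is the *induced* subgraph on
{i} ∪ neighbors(i), where the neighbor set is the union of in- and
out-neighbors.  Induced means neighbor–neighbor edges are included, not
only edges incident to *i*; this choice is forced by the reference
subgraph-degree table, which is only reproducible with the mutual edges
between the focal node's neighbors counted.  The union reading of
"neighbors" cannot be discriminated on fully reciprocal networks, so the
test suite exercises it against a brute-force oracle on synthetic
non-reciprocal digraphs.

**Subgraph degree centrality (SDC).** In-degree plus out-degree within
Gᵢ.  For undirected networks, the number of adjacent members (the
symmetric storage would otherwise double-count every tie).

**Structural entropy** is the base-10 Shannon entropy of the normalized
SDC distribution over Gᵢ's members; **frequency entropy** is the entropy
of i's normalized out-edge weights (incident weights when undirected —
each undirected tie contributes once).  Degenerate distributions (no
edges, single edge) have entropy 0, with 0·log 0 := 0 throughout.  Both
entropies depend only on proportions, so all scores are invariant under a
global rescaling of the weights; the entropies are bounded by log₁₀(M+1)
and log₁₀(M) for M neighbors.

**Two-hop propagation.** Targets are nodes p ≠ i reachable via i→j→p
following edge direction at both hops, excluding i's one-hop
out-neighbors.  Per target, influence is mean(LI_i·LI_j) over the
intermediates j; the indirect influence II_i is the mean over the
*distinct* two-hop targets, and 0 when there are none.  Propagation depth
is fixed at two: the model's premise is that influence is not meaningfully
detectable further out, and no deeper variant is offered.

**Ranking.** I_i = θ₁·LI_i + θ₂·II_i, sorted descending; ties broken by
ascending node identifier and flagged in a `tied` column, since silent
tie-breaking would make published rankings irreproducible.

## Parameters

| parameter | default | meaning |
|---|---|---|
| ω₁, ω₂ | 0.4, 0.6 | weight of structural vs frequency entropy in LI |
| θ₁, θ₂ | 0.6, 0.4 | weight of local vs indirect influence in I |
| log base | 10 | entropy units; any base > 0, ≠ 1 rescales all scores monotonically |

The defaults are the published reference setting; both pairs must be
nonnegative and sum to 1 (validated).  With θ₂ = 0 the ranking reduces to
the local-influence ranking, a property the tests assert.

The claim that these coefficients keep influence in [0, 1] holds only for
small neighborhoods (roughly ≤ 10 neighbors under base-10 entropy) and is
treated as a description of small examples, not an enforced invariant.

## Known inconsistencies in the reference example

The published 8-node worked example contains two arithmetic slips, which
this implementation deliberately does not reproduce:

1. Node C's local influence is printed as 0.4955 where the definitions
   give 0.4995 (a transposed digit).  The printed value was evidently used
   downstream, so the reference table's indirect influences for B and E
   (0.3713, 0.3619) and total for B (0.5249) differ from the consistent
   values (0.3721, 0.3626, 0.5252) in the fourth decimal place.  E's
   printed total (0.5521) additionally disagrees with its own printed
   components (0.6·0.6956 + 0.4·0.3619 = 0.5621).
2. Node H's printed indirect influence divides its three two-hop terms
   by 2; every other node divides by its two-hop target count.  The
   uniform definition (divide by the number of distinct targets) is
   applied to all nodes.

The final ranking E, B, D, C, G, F, A, H is unaffected and reproduced
exactly.  Acceptance tests assert the printed table as printed, so the
assertions covering the slipped entries fail by design and document the
discrepancy rather than masking it.

## Baseline centralities

The evaluation protocol compares against degree, betweenness, closeness
and eigenvector centrality.  Published comparisons rarely state whether
these use weights or direction, so the conventions are explicit,
switchable, and recorded in each result's metadata:

* degree — unweighted total (in+out) degree;
* betweenness — exact Brandes on the directed graph with distances
  1/weight (strong ties are short), unnormalized;
* closeness — harmonic centrality on outgoing 1/weight distances,
  normalized by n−1 (the harmonic form is well defined on weakly
  connected digraphs, where classic closeness is not; a
  reachable-component-scaled variant is available);
* eigenvector — power iteration on the weighted in-edge adjacency,
  identity-shifted so periodic (e.g. bipartite) structures converge,
  L2-normalized, tolerance 1e-8, hard 1000-iteration cap with an explicit
  error.  On near-acyclic digraphs the spectrum is degenerate and the
  method legitimately fails to converge; tests treat that outcome as
  label-invariant behavior, not an error.

## SI spreading simulator

Discrete-time, synchronous susceptible–infectious dynamics.  Per step,
every susceptible node i is challenged independently by each infected
in-neighbor j across the edge j→i with probability p(w_ji); infections
apply at the step boundary; infected nodes never recover.  Two weight
forms: `1−(1−β)^w` (default; the edge bundles w unit contacts) and
`(w/w_max)^α`.  Transmission follows edge direction — the weight counts
interactions *in that direction* — and undirected networks carry the tie
weight both ways.

The implementation accumulates per-node log-survival probabilities with a
sparse matrix product, which is exactly equivalent to drawing the
individual Bernoulli challenges; certain infections (p = 1) use a sentinel
log-survival that underflows to zero survival.  Randomness is fully
determined by `rng_seed` via spawned per-replicate substreams, and method
comparisons reuse the same seed for every (method, k) cell so all methods
face identical noise.  Correctness is checked against the closed form
1−(1−β)^t on a two-node chain and against exact Markov-chain enumeration
of the full infected-set distribution on a four-node graph.

There is no published β or horizon for the original full-scale curves, so
those figures are not quantitatively reproducible; the package reproduces
the *protocol* (top-k seeding, mean over replicates, k sweep) and the
tests assert its qualitative laws: spread non-decreasing in time, in β and
(statistically) in k, for all five ranking methods.

## Synthetic networks

`random_network` samples each ordered pair independently (G(n, p) on
arcs), then augments each arc with its reverse with probability
`reciprocity` — the toy example is fully reciprocal while real directed
networks are not, and only non-reciprocal graphs distinguish in- from
out-neighbor conventions.  The base arc probability is solved from the
requested density or mean out-degree accounting for the augmentation.
Weights are i.i.d. uniform-integer 1..wmax (default, matching the toy
network's 1–5 flight counts), geometric, or lognormal.  An empty draw is
resampled from a fresh substream (≤ 100 attempts) so every network has an
edge.  The generator does not attempt to replicate the degree
distributions or clustering of any real dataset: passing tests show the
algorithms' internal consistency and qualitative behavior, not performance
on heavy-tailed empirical networks.

## Problem sizes and determinism

Test and acceptance workloads are desk-scale by design: the worked example
(8 nodes) verifies numeric fidelity; oracle equivalence uses 50 random
graphs of ≤ 12 nodes where brute-force enumeration is exact (1e-12); the
spreading protocol runs on a seeded 300-node network with k ∈ {5, 10, 20},
two β values and 200 replicates, large enough for the monotonicity laws to
hold with common-seed noise.  Every stochastic component takes an explicit
seed, and identical configurations give bit-identical results.

## Limitations

* Negative or zero weights are rejected: the entropies require positive
  arguments.  Signed and bipartite reputation networks are out of scope.
* Nodes with few, even ties in small neighborhoods can be
  indistinguishable (equal entropies), as can isolated nodes (all zero).
* Only edge lists are read; no GraphML/GEXF.
* SIR/SIS/threshold dynamics and continuous-time formulations are not
  implemented.
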