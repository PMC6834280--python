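# Methods

## Model

A directed hypergraph H = (V, E) holds one hyperedge e = (T_e, H_e) per
biochemical reaction, with the reactants and control elements (catalysts,
regulators) in the tail and the products in the head. Tails and heads are
non-empty by construction: an empty tail would make a hyperedge vacuously
traversable and an empty head carries no information, and curated reaction
tables contain neither once degenerate rows are dropped (the reaction-table
loader drops and logs them). Hyperedges with identical member sets under
distinct identifiers are kept — they are distinct reactions and have no effect
on connectivity. A node may appear in both the tail and head of one hyperedge
(auto-catalysis); the traversal semantics below apply to it mechanically.

**B-connectivity.** A node u is B-connected to a source set S if u ∈ S or
some hyperedge e has u ∈ H_e and every member of T_e B-connected to S. The
`b_visit` traversal maintains, per hyperedge, a counter of tail members
reached; a hyperedge is traversed — its head merged — exactly when the
counter reaches the tail size. Besides the connected set B(H, S) it returns
the *traversed* hyperedges X and the *restrictive* hyperedges R(H, S): those
with at least one but not all tail members connected. The queue is FIFO
seeded in sorted node order so traversal logs are reproducible; the output
sets are order-invariant (property-tested against randomly permuted queue
disciplines).

**B-relaxation distance.** Layers are defined by

    B_0 = B(H, S),  R_0 = R(H, S)
    B_k = ⋃_{e ∈ R_{k−1}} B(H, H_e),   R_k = ⋃_{e ∈ R_{k−1}} R(H, H_e)

and dist(v) is the first k with v ∈ B_k (source nodes are in B_0, so their
distance is 0; when a node appears in several layers the minimum governs).
Seeding each inner visit with H_e alone — not the accumulated connected set —
is deliberate: it guarantees that exactly one restrictive hyperedge per
iteration is granted along any dependency chain, which is what makes dist a
count of forced relaxations. The alternative "cumulative seeding" reading
(seed each inner visit with everything connected so far) yields a different,
laxer quantity; it is documented here as a variant and intentionally not
implemented.

Three implementations are provided and proven equivalent on randomized
instances:

1. `b_relaxation_oracle` evaluates the recurrence literally, one fresh
   `b_visit` per restrictive hyperedge per iteration. It terminates when the
   current restrictive set contains no hyperedge not already expanded (the
   layer map from a hyperedge's head depends only on the hyperedge, so a
   repeated restrictive set can never contribute new nodes). This is the
   reference implementation; it is deliberately cache-free.
2. `b_relaxation` adds a `seen` dictionary: a restrictive hyperedge already
   traversed inside an earlier inner visit is skipped, because its head's
   B-connected set is contained in a set merged at a smaller k (if e was
   traversed during the visit from H_e′, then H_e ⊆ B(H, H_e′), and
   B-connectivity is monotone and idempotent, so B(H, H_e) ⊆ B(H, H_e′)).
   Restrictive sets may still *contain* seen hyperedges; only their
   re-expansion is skipped. Termination is governed by the existence of
   unseen restrictive hyperedges.
3. `b_relaxation_fast` replaces every inner visit with a lookup into a table
   of `b_visit(H, H_e)` results precomputed once per hypergraph
   (O(|E|·size(H)), where size(H) = Σ|T_e| + |H_e|). After the shared
   precomputation each source costs roughly one initial visit plus set
   unions, which is what makes all-sources surveys tractable. The table
   stores a structure fingerprint and refuses to serve a mutated hypergraph.

Distance 0 recovers B-connectivity exactly; finite distance coincides exactly
with reachability in the bipartite entity/reaction graph (one reaction node
per hyperedge, tail → reaction → head arcs). Both identities are enforced as
acceptance tests, not assumed.

## Influence score and permutation null

For pathways P_S, P_T ⊆ V, with B_≤k the set of nodes at distance ≤ k from
P_S,

    s_k(S, T) = |(B_≤k ∩ P_T) \ (P_S ∩ P_T)| / |B_≤k \ (P_S ∩ P_T)| ∈ [0, 1].

The initial overlap P_S ∩ P_T is discounted from numerator and denominator so
the score measures newly exerted influence rather than shared annotation.
When the denominator is empty the score is defined as 0: a source reaching
nothing outside the overlap exerts no measurable influence (the convention
only fires for sources whose reach is confined to the overlap). Pathway
member sets are intersected with the hypergraph's node set at attachment;
members in no reaction carry no topological signal.

The null model permutes memberships while freezing the overlap structure.
Molecules and the non-empty Venn regions of the collection form a bipartite
permutation graph in which every molecule has degree one (its membership
pattern); a degree-preserving edge swap picks two molecules uniformly and
exchanges their region assignments when the regions differ, rejecting (but
counting) proposals that would duplicate an edge. Region sizes are invariant,
hence every pathway size and every pairwise intersection count is preserved
exactly — verified for 1,000 permutations at the default 10,000 swaps.
Defaults: n_perm = 1000, n_swaps = 10,000, both configurable. A pair is
reported significant when no permutation attains the observed score
(n_ge = 0); no multiple-testing correction is applied across pairs, matching
the raw-count reporting convention for this statistic. Permuted runs reuse
the original head-visit table — the hypergraph is unchanged, only the source
member set moves.

## Representations and filtering

The SIF → directed-graph conversion needs a per-relation direction policy.
Only "neighbor-of: ignore" is forced (it is purely positional); the shipped
default treats the control-type relations (controls-state-change-of,
controls-expression-of, controls-transport-of, controls-phosphorylation-of,
catalysis-precedes) as directed and the binding relations (in-complex-with,
interacts-with) as bidirected, following the SIF dialect's semantics. The
policy is an argument and a config key, not a constant.

Bipartite reaction nodes are named `R::<hyperedge id>`; a collision with an
entity id is an error. Distances on the bipartite graph are raw BFS hops
(entities sit at even distances); no halving is applied, since cross-
representation comparisons here are qualitative.

Node filtering removes a set (ubiquitous small molecules, blacklists) from
every tail and head, dropping hyperedges left with an empty side; the
operation reports how many hyperedges were altered and dropped, is
idempotent, and is identity for an empty removal set.

## Synthetic data

The random generator draws, per hyperedge, tail and head sizes uniformly from
configured ranges (defaults 1–3 each — small multi-molecule reactions, the
typical regime for curated signaling reactions) over disjoint member sets,
with a configurable fraction of nodes (default 0.1) tagged as small
molecules. It emulates the *local* shape of reaction data — many-to-many
edges with small cardinalities — and makes no attempt to match a real
database's degree distribution, modularity or annotation structure; passing
tests on it demonstrates algorithmic correctness, not biological recall on
real databases.

The planted chain forces known distances: the source feeds a level-0 node,
and each of D junction hyperedges carries one permanently unreachable tail
blocker, so the terminal node's distance is exactly D by construction.
Synthetic pathway collections realize a requested pairwise-overlap matrix
with mutually exclusive two-way regions (all triple intersections empty — a
pairwise matrix does not determine higher-order structure, so the simplest
consistent region system is used; infeasible requests error out). The
planted influence bundle puts the chain source in one pathway, all nodes at
distance 1..D in the target pathway, and decoys on isolated background
nodes, giving a pair whose observed score is high while any
membership permutation scatters it.

## Problem sizes and numerical choices

- Equivalence checks run on 100 random hypergraphs of 10–30 nodes plus all
  fixtures; limit-recovery on 50 instances of 18 nodes with every node as a
  source; the speedup measurement uses 2,000 nodes / 3,500 hyperedges and 100
  sources, where the precomputed variant runs an order of magnitude faster
  than the per-source algorithm (about 20× measured, precomputation
  excluded). These sizes exercise every code path while keeping the full
  suite around a minute.
- Infinity is the distance of unreachable nodes and serializes as the literal
  string `inf` in TSV output.
- All writers sort keys, so outputs are byte-identical for a given seed; all
  generators take explicit integer seeds and use integer-only randomness for
  structural choices, so results are platform-independent.
- The Kruskal-Wallis comparison of score distributions degenerates when every
  score in every category is identical; that case is reported as H = 0,
  p = 1 (no separation) rather than an error.
- Interaction pairs are undirected; by default a pair counts as connected
  when either direction connects, with a "both directions" mode available.
  Channels with homology-transferred evidence and curated-database channels
  are excluded from enrichment comparisons by default, as their scores are
  not independent of the pathway annotations being tested.

## Known limitations

- Hypernodes (complexes as node sets), signed activation/inhibition edges,
  compound-graph traversal and shortest-hyperpath optimization are out of
  scope.
- BioPAX/OWL parsing is not included: the hypergraph builder consumes a
  pre-extracted reaction table (reaction id, reactants, controllers,
  products).
- The pairwise-overlap realization of synthetic pathway collections cannot
  express deliberate triple overlaps.
- The permutation null preserves overlap structure but not any relationship
  between membership and topology other than what the observed collection
  has; power estimates on synthetic bundles transfer to real data only
  qualitatively.
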