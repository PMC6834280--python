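"""Alternative representations of a reaction network and conversions between them.

Four representations of the same curated reaction data are in play:

- the directed *hypergraph* (the primary structure, :mod:`brelax.hypergraph`),
  built from a reaction table by placing reactants and controllers in the tail
  and products in the head of one hyperedge per reaction;
- the *bipartite graph*, with one reaction node per hyperedge, tail entities
  feeding the reaction node and the reaction node feeding head entities;
- the *directed graph* over molecules, built from SIF binary relations
  (directed regulatory relations give one arc, symmetric binding relations two,
  and purely positional relations such as neighbor-of are dropped);
- plain BFS distances on either graph.

Graphs are held as :class:`networkx.DiGraph` objects so the standard graph
toolbox applies directly.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import networkx as nx

from .hypergraph import DirectedHypergraph, NodeAttributes

__all__ = [
    "DEFAULT_RELATION_POLICY",
    "REACTION_PREFIX",
    "hypergraph_to_bipartite",
    "sif_to_directed_graph",
    "build_hypergraph_from_reactions",
    "filter_hypergraph",
    "bfs_distances",
]

logger = logging.getLogger(__name__)

REACTION_PREFIX = "R::"

# Direction policy for PathwayCommons SIF binary relations.  Only neighbor-of
# is unambiguously positional; control-type relations are directed and binding
# relations symmetric, per the SIF dialect's semantics.  User-overridable.
DEFAULT_RELATION_POLICY: Dict[str, str] = {
    "controls-state-change-of": "directed",
    "controls-expression-of": "directed",
    "controls-transport-of": "directed",
    "controls-phosphorylation-of": "directed",
    "catalysis-precedes": "directed",
    "in-complex-with": "bidirected",
    "interacts-with": "bidirected",
    "neighbor-of": "ignore",
}


def hypergraph_to_bipartite(h: DirectedHypergraph) -> nx.DiGraph:
    """Convert a hypergraph to its bipartite entity/reaction digraph.

    Every hyperedge e becomes a reaction node ``R::<edge id>``; each tail
    entity gets an arc into the reaction node and the reaction node gets an arc
    to each head entity.  The result has |V| + |E| nodes and size(H) arcs.
    Entity nodes carry ``kind='entity'``, reaction nodes ``kind='reaction'``.
    """
    g = nx.DiGraph()
    g.add_nodes_from(h.nodes, kind="entity")
    for eid, (tail, head) in h.hyperedges.items():
        rnode = REACTION_PREFIX + eid
        if rnode in h.nodes:
            raise ValueError(
                f"reaction node id {rnode!r} collides with an entity node"
            )
        g.add_node(rnode, kind="reaction")
        for v in tail:
            g.add_edge(v, rnode)
        for v in head:
            g.add_edge(rnode, v)
    return g


def sif_to_directed_graph(
    records: Iterable[Sequence[str]],
    relation_policy: Mapping[str, str] | None = None,
    unknown: str = "ignore",
) -> nx.DiGraph:
    """Build a directed graph from (source, relation, target) SIF records.

    ``relation_policy`` maps each relation to ``directed`` (one arc
    source->target), ``bidirected`` (both arcs) or ``ignore``.  Relations
    absent from the policy are handled per ``unknown``.
    """
    policy = dict(DEFAULT_RELATION_POLICY if relation_policy is None else relation_policy)
    g = nx.DiGraph()
    for i, rec in enumerate(records, start=1):
        if len(rec) != 3:
            raise ValueError(f"SIF record {i}: expected 3 fields, got {len(rec)}")
        src, rel, dst = rec
        action = policy.get(rel, unknown)
        if action == "ignore":
            continue
        g.add_edge(src, dst)
        if action == "bidirected":
            g.add_edge(dst, src)
        elif action != "directed":
            raise ValueError(f"SIF record {i}: unknown policy action {action!r}")
    return g


def build_hypergraph_from_reactions(
    rows: Iterable[Tuple[str, Iterable[str], Iterable[str], Iterable[str]]],
) -> DirectedHypergraph:
    """Build a hypergraph from (reaction id, reactants, controllers, products).

    The tail of each hyperedge is reactants union controllers; the head is the
    products — a reaction fires only when its inputs and its catalysts/
    regulators are all available.  Rows whose tail or head would be empty are
    dropped with a log message; duplicate reaction ids are an error.
    """
    h = DirectedHypergraph()
    seen_ids = set()
    for rid, reactants, controllers, products in rows:
        if rid in seen_ids:
            raise ValueError(f"duplicate reaction id {rid!r}")
        seen_ids.add(rid)
        tail = set(reactants) | set(controllers)
        head = set(products)
        if not tail or not head:
            logger.warning("dropping degenerate reaction %r (empty tail or head)", rid)
            continue
        h.add_hyperedge(rid, tail, head)
    return h


def filter_hypergraph(
    h: DirectedHypergraph,
    remove: Iterable[str],
    attrs: NodeAttributes | None = None,
) -> Tuple[DirectedHypergraph, int, int]:
    """Remove a node set from a hypergraph, pruning degenerate hyperedges.

    Removed nodes are deleted from every tail and head; a hyperedge whose tail
    or head becomes empty is dropped.  Returns the filtered hypergraph, the
    number of *altered* hyperedges (membership changed, dropped ones included)
    and the number dropped.  ``attrs`` is only consulted to sanity-check the
    removal set; attribute tables keyed by node id remain usable as-is.
    """
    rm = set(remove)
    unknown = rm - h.nodes
    if unknown:
        raise KeyError(f"cannot remove unknown node(s): {sorted(unknown)}")
    out = DirectedHypergraph(nodes=h.nodes - rm)
    altered = dropped = 0
    for eid, (tail, head) in h.hyperedges.items():
        new_tail, new_head = tail - rm, head - rm
        if new_tail != tail or new_head != head:
            altered += 1
        if not new_tail or not new_head:
            dropped += 1
            continue
        out.add_hyperedge(eid, new_tail, new_head)
    return out, altered, dropped


def bfs_distances(g: nx.DiGraph, source: Iterable[str]) -> Dict[str, float]:
    """Unweighted shortest-path distance from a source set to every node.

    Unreachable nodes map to ``inf``.  Multi-node sources are treated as one
    super-source at distance 0.
    """
    src = set(source)
    unknown = src - set(g.nodes)
    if unknown:
        raise KeyError(f"unknown source node(s): {sorted(unknown)}")
    dist: Dict[str, float] = {v: math.inf for v in g.nodes}
    for s in src:
        for v, d in nx.single_source_shortest_path_length(g, s).items():
            if d < dist[v]:
                dist[v] = d
    return dist
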