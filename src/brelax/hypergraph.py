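"""Directed hypergraph data model and B-visit traversal.

A directed hypergraph H = (V, E) has a node set V and hyperedges e = (T_e, H_e),
each connecting a non-empty *tail* set T_e (reaction inputs: reactants and
controllers) to a non-empty *head* set H_e (reaction outputs).  The biologically
meaningful notion of reachability on such a structure is *B-connectivity*: a
hyperedge may be traversed only once every node in its tail is already
connected, i.e. a product is reachable only when all reactants are present.

``b_visit`` computes the B-connected set from a source set, together with the
*traversed* hyperedges (all tail members connected) and the *restrictive*
hyperedges (at least one but not all tail members connected — reachable but not
traversable).  The restrictive set drives the relaxation machinery in
:mod:`brelax.relaxation`.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Set, Tuple

__all__ = [
    "DirectedHypergraph",
    "NodeAttributes",
    "BVisitResult",
    "validate_hypergraph",
    "size_of",
    "b_visit",
    "classify_hyperedges",
]

ENTITY_TYPES = ("protein", "smallmolecule", "complex", "family", "other")


class DirectedHypergraph:
    """A directed hypergraph with opaque string node identifiers.

    Parameters
    ----------
    nodes
        Iterable of node identifiers.  Nodes referenced by hyperedges are added
        automatically; isolated nodes are permitted.
    hyperedges
        Mapping from hyperedge id to a ``(tail, head)`` pair of node-id
        iterables.  Tail and head must both be non-empty; degenerate edges are
        rejected at construction (an empty tail would be vacuously traversable,
        which curated reaction data never exercises).
    """

    def __init__(
        self,
        nodes: Iterable[str] = (),
        hyperedges: Mapping[str, Tuple[Iterable[str], Iterable[str]]] | None = None,
    ):
        self._nodes: Set[str] = set(nodes)
        self._edges: Dict[str, Tuple[frozenset, frozenset]] = {}
        # node -> ids of hyperedges whose tail contains it (forward star)
        self._tail_index: Dict[str, Set[str]] = {}
        if hyperedges:
            for eid, (tail, head) in hyperedges.items():
                self.add_hyperedge(eid, tail, head)

    # -- construction -----------------------------------------------------

    def add_node(self, node: str) -> None:
        self._nodes.add(node)

    def add_hyperedge(self, eid: str, tail: Iterable[str], head: Iterable[str]) -> None:
        tail_f, head_f = frozenset(tail), frozenset(head)
        if eid in self._edges:
            raise ValueError(f"duplicate hyperedge id {eid!r}")
        if not tail_f or not head_f:
            raise ValueError(f"hyperedge {eid!r} has an empty tail or head")
        self._edges[eid] = (tail_f, head_f)
        self._nodes.update(tail_f)
        self._nodes.update(head_f)
        for v in tail_f:
            self._tail_index.setdefault(v, set()).add(eid)

    # -- accessors --------------------------------------------------------

    @property
    def nodes(self) -> Set[str]:
        return self._nodes

    @property
    def hyperedges(self) -> Dict[str, Tuple[frozenset, frozenset]]:
        return self._edges

    def tail(self, eid: str) -> frozenset:
        return self._edges[eid][0]

    def head(self, eid: str) -> frozenset:
        return self._edges[eid][1]

    def edges_with_tail_member(self, node: str) -> Set[str]:
        """Hyperedge ids whose tail contains ``node``."""
        return self._tail_index.get(node, set())

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, node: str) -> bool:
        return node in self._nodes

    def __eq__(self, other) -> bool:
        if not isinstance(other, DirectedHypergraph):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"DirectedHypergraph({len(self._nodes)} nodes, "
            f"{len(self._edges)} hyperedges)"
        )

    def fingerprint(self) -> int:
        """Structure hash used to detect stale precomputation tables."""
        return hash(
            (
                frozenset(self._nodes),
                frozenset((eid, t, h) for eid, (t, h) in self._edges.items()),
            )
        )


@dataclass
class NodeAttributes:
    """Per-node entity type and display name.

    ``entity_type`` is one of ``protein``, ``smallmolecule``, ``complex``,
    ``family`` or ``other`` — the categories curated reaction databases attach
    to their physical entities.  Used chiefly to select small molecules for
    pruning (ubiquitous metabolites such as ATP and water connect functionally
    unrelated reactions and dominate naive reachability).
    """

    entity_type: Dict[str, str] = field(default_factory=dict)
    display_name: Dict[str, str] = field(default_factory=dict)

    def set(self, node: str, entity_type: str = "other", display_name: str = "") -> None:
        if entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {entity_type!r}")
        self.entity_type[node] = entity_type
        self.display_name[node] = display_name or node

    def of_type(self, entity_type: str) -> Set[str]:
        return {n for n, t in self.entity_type.items() if t == entity_type}

    def check_against(self, h: DirectedHypergraph) -> list[str]:
        return [
            f"attribute for unknown node {n!r}" for n in self.entity_type if n not in h
        ]


@dataclass(frozen=True)
class BVisitResult:
    """Output of one B-visit traversal.

    Attributes
    ----------
    connected
        The B-connected node set B(H, S); always a superset of the source.
    restrictive
        Hyperedges with >= 1 but < |T_e| tail members connected: reachable but
        not traversable.
    traversed
        Hyperedges whose entire tail ended up connected.
    """

    connected: frozenset
    restrictive: frozenset
    traversed: frozenset


def validate_hypergraph(h: DirectedHypergraph) -> list[str]:
    """Return a list of invariant-violation descriptions (empty if valid)."""
    violations = []
    for eid, (tail, head) in h.hyperedges.items():
        if not tail:
            violations.append(f"hyperedge {eid!r} has an empty tail")
        if not head:
            violations.append(f"hyperedge {eid!r} has an empty head")
        for v in tail | head:
            if v not in h.nodes:
                violations.append(f"hyperedge {eid!r} references unknown node {v!r}")
    return violations


def size_of(h: DirectedHypergraph) -> int:
    """Sum of hyperedge cardinalities, sum over e of |T_e| + |H_e|."""
    return sum(len(t) + len(hd) for t, hd in h.hyperedges.values())


def hyperedge_cardinality(h: DirectedHypergraph, eid: str) -> int:
    """|T_e| + |H_e| for a single hyperedge."""
    tail, head = h.hyperedges[eid]
    return len(tail) + len(head)


def _check_source(h: DirectedHypergraph, source: Iterable[str]) -> Set[str]:
    src = set(source)
    if not src:
        raise ValueError("source set must be non-empty")
    unknown = src - h.nodes
    if unknown:
        raise KeyError(f"unknown source node(s): {sorted(unknown)}")
    return src


def b_visit(h: DirectedHypergraph, source: Iterable[str]) -> BVisitResult:
    """B-connectivity traversal from a source set.

    A FIFO queue seeded with the sorted source nodes is processed; each
    hyperedge keeps a counter of connected tail members and is traversed — its
    head merged into the connected set — exactly when the counter reaches the
    tail size.  The output sets are invariant to the queue processing order;
    sorting only fixes the traversal log for reproducibility.
    """
    src = _check_source(h, source)
    count: Dict[str, int] = {}
    connected: Set[str] = set(src)
    traversed: Set[str] = set()
    queue = deque(sorted(src))
    while queue:
        v = queue.popleft()
        for eid in h.edges_with_tail_member(v):
            c = count.get(eid, 0) + 1
            count[eid] = c
            if c == len(h.tail(eid)):
                head = h.head(eid)
                queue.extend(sorted(head - connected))
                connected |= head
                traversed.add(eid)
    restrictive = {
        eid
        for eid, c in count.items()
        if 0 < c < len(h.tail(eid))
    }
    return BVisitResult(frozenset(connected), frozenset(restrictive), frozenset(traversed))


def classify_hyperedges(
    h: DirectedHypergraph, source: Iterable[str]
) -> Dict[str, str]:
    """Classify every hyperedge relative to a source set.

    Categories: ``traversable`` (whole tail B-connected), ``restrictive``
    (reachable but not traversable), ``untouched`` (no tail member connected).
    Reachable = traversable or restrictive.
    """
    res = b_visit(h, source)
    out = {}
    for eid in h.hyperedges:
        if eid in res.traversed:
            out[eid] = "traversable"
        elif eid in res.restrictive:
            out[eid] = "restrictive"
        else:
            out[eid] = "untouched"
    return out
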