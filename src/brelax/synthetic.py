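"""Synthetic hypergraphs, fixtures and pathway collections.

Everything downstream of the raw data formats is testable on instances built
here: small hand-traceable fixtures, seeded random hypergraphs, planted-chain
instances whose B-relaxation distances are forced by construction, and pathway
collections with exact pairwise overlaps and an optional planted influence
pair.  All generators are deterministic under their seed and use integer-only
randomness for structure choices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Sequence, Tuple

import numpy as np

from .hypergraph import DirectedHypergraph, NodeAttributes, validate_hypergraph
from .influence import PathwayCollection
from .relaxation import b_relaxation_oracle

__all__ = [
    "GeneratorConfig",
    "toy_fixtures",
    "generate_random_hypergraph",
    "generate_planted_chain",
    "generate_synthetic_pathways",
    "planted_influence_bundle",
]


@dataclass
class GeneratorConfig:
    """Parameters for random hypergraph generation.

    Tail and head sizes are drawn uniformly from the given inclusive ranges;
    within one hyperedge the tail and head are disjoint and sampled without
    replacement (reactant-equals-product loops are rare in curated reactions
    and off by default).  ``smallmolecule_fraction`` of the nodes are tagged as
    small molecules in the accompanying attribute table.
    """

    n_nodes: int = 50
    n_hyperedges: int = 80
    tail_size: Tuple[int, int] = (1, 3)
    head_size: Tuple[int, int] = (1, 3)
    smallmolecule_fraction: float = 0.1
    allow_tail_head_overlap: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 1 or self.n_hyperedges < 0:
            raise ValueError("n_nodes >= 1 and n_hyperedges >= 0 required")
        for lo, hi in (self.tail_size, self.head_size):
            if lo < 1 or hi < lo:
                raise ValueError("size ranges must satisfy 1 <= lo <= hi")
        needed = self.tail_size[1] + (
            0 if self.allow_tail_head_overlap else self.head_size[1]
        )
        if self.n_nodes < max(needed, self.head_size[1]):
            raise ValueError("n_nodes too small for the requested tail+head sizes")
        if not 0 <= self.smallmolecule_fraction <= 1:
            raise ValueError("smallmolecule_fraction must be in [0, 1]")


def toy_fixtures() -> Dict[str, Tuple[DirectedHypergraph, FrozenSet[str]]]:
    """Named hand-traceable fixtures with their conventional source sets.

    ``toy1``: six nodes, three hyperedges — ({a,b},{c}), ({c},{d}),
    ({d,f},{e}).  From {a,b} the B-connected set is {a,b,c,d} with ({d,f},{e})
    restrictive.

    ``relax3``: a three-junction chain in the spirit of a staged relaxation
    example: from {a,b} node ``r`` has B-relaxation distance exactly three,
    each junction hyperedge carrying one permanently unreachable tail member.
    Both properties are verified with the literal-definition oracle at build
    time.
    """
    toy1 = DirectedHypergraph(
        hyperedges={
            "e1": ({"a", "b"}, {"c"}),
            "e2": ({"c"}, {"d"}),
            "e3": ({"d", "f"}, {"e"}),
        }
    )

    relax3 = DirectedHypergraph(
        hyperedges={
            "e1": ({"a", "b"}, {"c"}),
            "j1": ({"c", "u1"}, {"d"}),
            "j2": ({"d", "u2"}, {"q"}),
            "j3": ({"q", "u3"}, {"r"}),
        }
    )

    fixtures = {"toy1": (toy1, frozenset({"a", "b"})), "relax3": (relax3, frozenset({"a", "b"}))}
    for name, (h, src) in fixtures.items():
        assert not validate_hypergraph(h), name
    assert b_relaxation_oracle(relax3, {"a", "b"}).dist["r"] == 3
    return fixtures


def generate_random_hypergraph(
    cfg: GeneratorConfig,
) -> Tuple[DirectedHypergraph, NodeAttributes]:
    """Seeded random hypergraph plus a node attribute table."""
    rng = np.random.default_rng(cfg.seed)
    nodes = [f"n{i:04d}" for i in range(cfg.n_nodes)]
    h = DirectedHypergraph(nodes=nodes)
    for j in range(cfg.n_hyperedges):
        t = int(rng.integers(cfg.tail_size[0], cfg.tail_size[1] + 1))
        s = int(rng.integers(cfg.head_size[0], cfg.head_size[1] + 1))
        if cfg.allow_tail_head_overlap:
            tail = rng.choice(cfg.n_nodes, size=t, replace=False)
            head = rng.choice(cfg.n_nodes, size=s, replace=False)
        else:
            both = rng.choice(cfg.n_nodes, size=t + s, replace=False)
            tail, head = both[:t], both[t:]
        h.add_hyperedge(
            f"e{j:04d}", {nodes[i] for i in tail}, {nodes[i] for i in head}
        )
    attrs = NodeAttributes()
    n_small = int(round(cfg.smallmolecule_fraction * cfg.n_nodes))
    small = set(rng.choice(cfg.n_nodes, size=n_small, replace=False).tolist())
    for i, n in enumerate(nodes):
        attrs.set(n, "smallmolecule" if i in small else "protein")
    return h, attrs


def generate_planted_chain(
    depth: int, branch_width: int = 1, seed: int = 0
) -> Tuple[DirectedHypergraph, FrozenSet[str], str]:
    """Chain whose terminal node has B-relaxation distance exactly ``depth``.

    The source feeds a level-0 node through an ordinary hyperedge.  Each of
    the ``depth`` junction hyperedges has the previous level's chain node plus
    one permanently unreachable blocker in its tail, so exactly one relaxation
    is forced per level; heads carry ``branch_width`` nodes (the chain node
    plus payload).  Returns (hypergraph, source set, terminal node id).
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if branch_width < 1:
        raise ValueError("branch_width must be >= 1")
    h = DirectedHypergraph()
    source = "src"
    h.add_hyperedge("e_root", {source}, {"c0"})
    for lvl in range(1, depth + 1):
        head = {f"c{lvl}"} | {f"p{lvl}_{b}" for b in range(1, branch_width)}
        h.add_hyperedge(f"j{lvl}", {f"c{lvl - 1}", f"u{lvl}"}, head)
    terminal = f"c{depth}"
    return h, frozenset({source}), terminal


def _feasible_overlaps(
    sizes: Sequence[int], overlaps: Dict[Tuple[int, int], int]
) -> None:
    for (i, j), c in overlaps.items():
        if i == j or c < 0:
            raise ValueError(f"bad overlap target ({i},{j})={c}")
    for i, size in enumerate(sizes):
        shared = sum(c for (a, b), c in overlaps.items() if i in (a, b))
        if shared > size:
            raise ValueError(
                f"pathway {i}: pairwise overlaps ({shared}) exceed its size ({size})"
            )


def generate_synthetic_pathways(
    h: DirectedHypergraph,
    sizes: Sequence[int],
    overlaps: Dict[Tuple[int, int], int] | None = None,
    planted_pair: Tuple[int, int] | None = None,
    planted_source_members: Iterable[str] | None = None,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> PathwayCollection:
    """Pathway collection over ``h`` with exact pairwise overlap counts.

    Overlaps are realized with mutually exclusive two-way regions (every
    triple intersection empty), which a pairwise matrix determines uniquely.
    When a ``planted_pair`` (source index, target index) is given, the source
    pathway receives ``planted_source_members`` verbatim and the target's
    exclusive members are drawn preferentially from nodes at small positive
    B-relaxation distance from that source, planting a genuine influence
    signal.  Raises when the targets cannot be realized within ``h``'s nodes.
    """
    rng = np.random.default_rng(seed)
    overlaps = {tuple(sorted(k)): v for k, v in (overlaps or {}).items()}
    _feasible_overlaps(sizes, overlaps)
    n = len(sizes)
    names = list(names) if names is not None else [f"P{i}" for i in range(n)]
    if len(names) != n:
        raise ValueError("names must match sizes")

    pool = sorted(h.nodes)
    rng.shuffle(pool)
    pool_iter = iter(pool)
    taken: set = set()

    def draw(k: int, prefer: List[str] | None = None) -> List[str]:
        out: List[str] = []
        if prefer:
            for v in prefer:
                if len(out) == k:
                    break
                if v not in taken:
                    out.append(v)
                    taken.add(v)
        while len(out) < k:
            try:
                v = next(pool_iter)
            except StopIteration:
                raise ValueError("not enough nodes in the hypergraph for the targets")
            if v not in taken:
                out.append(v)
                taken.add(v)
        return out

    members: List[set] = [set() for _ in range(n)]

    if planted_pair is not None:
        si, ti = planted_pair
        src_members = list(planted_source_members or [])
        if not src_members:
            raise ValueError("planted_pair requires planted_source_members")
        for v in src_members:
            if v in taken or v not in h.nodes:
                raise ValueError(f"planted source member {v!r} unavailable")
            taken.add(v)
        members[si].update(src_members)
        relax = b_relaxation_oracle(h, set(src_members))
        downstream = sorted(
            (v for v, d in relax.dist.items() if 0 < d < np.inf),
            key=lambda v: (relax.dist[v], v),
        )
    else:
        si = ti = -1
        downstream = []

    # shared two-way regions first, then exclusive remainders
    for (i, j), c in overlaps.items():
        shared = draw(c)
        members[i].update(shared)
        members[j].update(shared)
    for i in range(n):
        deficit = sizes[i] - len(members[i])
        if deficit < 0:
            raise ValueError(f"pathway {i} overfilled; infeasible targets")
        prefer = downstream if i == ti else None
        members[i].update(draw(deficit, prefer))

    return PathwayCollection(dict(zip(names, members)), h)


def planted_influence_bundle(
    seed: int = 0,
    depth: int = 3,
    branch_width: int = 4,
    n_decoys: int = 4,
    decoy_size: int = 8,
) -> Tuple[DirectedHypergraph, PathwayCollection, str, str, int]:
    """Hypergraph plus pathway collection with one strongly planted pair.

    A planted chain provides the topology; the source pathway holds the chain
    source and its level-0 node, the target pathway holds every node at
    relaxation distance 1..depth, and decoy pathways sit on isolated
    background nodes.  Returns (hypergraph, collection, source name, target
    name, k) with k = depth, at which the planted pair's influence score is
    near 1 while any membership permutation scatters it.
    """
    h, src, _terminal = generate_planted_chain(depth, branch_width, seed)
    rng = np.random.default_rng(seed)
    background = [f"bg{i:03d}" for i in range(n_decoys * decoy_size + 10)]
    for b in background:
        h.add_node(b)

    relax = b_relaxation_oracle(h, src)
    target_members = {v for v, d in relax.dist.items() if 0 < d < np.inf}
    source_members = set(src) | {v for v, d in relax.dist.items() if d == 0}

    pathways: Dict[str, set] = {
        "SRC": source_members,
        "TGT": target_members,
    }
    picks = rng.permutation(len(background))
    for d in range(n_decoys):
        ids = picks[d * decoy_size : (d + 1) * decoy_size]
        pathways[f"DECOY{d}"] = {background[i] for i in ids}
    return h, PathwayCollection(pathways, h), "SRC", "TGT", depth
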