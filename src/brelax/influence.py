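"""Pathway influence scoring with an overlap-preserving permutation null.

Given a source pathway P_S and a target pathway P_T on the same hypergraph, the
influence score at relaxation level k is

    s_k(S, T) = |(B_<=k(P_S) n P_T) \\ (P_S n P_T)|  /  |B_<=k(P_S) \\ (P_S n P_T)|

i.e. of everything newly reachable from the source pathway within k
relaxations (the initial membership overlap discounted from both counts), the
fraction that belongs to the target pathway.  The score lies in [0, 1]; it is
defined as 0 when the denominator is empty (a source reaching nothing outside
the overlap exerts no measurable influence).

Significance is assessed against a null that shuffles pathway memberships
while preserving every pairwise overlap exactly.  Molecules and the non-empty
Venn regions of the pathway collection form a bipartite *permutation graph*
(each molecule has degree one, linked to the region encoding its membership
pattern); degree-preserving edge swaps exchange the region assignments of two
molecules in different regions, keeping every region's size — hence every
pairwise intersection — fixed.  A pair is called significant when no
permutation reaches the observed score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Set, Tuple

import numpy as np
import pandas as pd

from .hypergraph import DirectedHypergraph
from .relaxation import (
    HeadVisitTable,
    RelaxationResult,
    b_relaxation_fast,
    precompute_head_visits,
)

__all__ = [
    "PathwayCollection",
    "InfluenceRecord",
    "PermutationGraph",
    "pathway_overlap",
    "influence_score",
    "influence_profile",
    "build_permutation_graph",
    "permute_memberships",
    "permutation_significance",
]


class PathwayCollection:
    """Named pathways, each a set of node identifiers.

    When attached to a hypergraph, member sets are intersected with the
    hypergraph's node set (members taking part in no reaction carry no
    topological information); a pathway left empty by that restriction, or
    empty to begin with, is rejected.
    """

    def __init__(
        self,
        pathways: Dict[str, Iterable[str]],
        hypergraph: DirectedHypergraph | None = None,
    ):
        self._pathways: Dict[str, FrozenSet[str]] = {}
        for name, members in pathways.items():
            m = frozenset(members)
            if hypergraph is not None:
                m = m & frozenset(hypergraph.nodes)
            if not m:
                raise ValueError(f"pathway {name!r} is empty (after restriction)")
            self._pathways[name] = m

    @property
    def names(self) -> List[str]:
        return sorted(self._pathways)

    def members(self, name: str) -> FrozenSet[str]:
        try:
            return self._pathways[name]
        except KeyError:
            raise KeyError(f"unknown pathway {name!r}") from None

    def items(self):
        return self._pathways.items()

    def __len__(self) -> int:
        return len(self._pathways)

    def __contains__(self, name: str) -> bool:
        return name in self._pathways

    def molecule_universe(self) -> FrozenSet[str]:
        out: Set[str] = set()
        for m in self._pathways.values():
            out |= m
        return frozenset(out)


@dataclass(frozen=True)
class InfluenceRecord:
    """Observed s_k for one (source, target) pathway pair with its null counts.

    ``n_ge`` counts permutations whose score is greater than or equal to the
    observed one; ``significant`` is True when that count is zero.
    """

    source: str
    target: str
    k: int
    score: float
    n_perm: int
    n_ge: int

    @property
    def significant(self) -> bool:
        return self.n_ge == 0


def pathway_overlap(p: PathwayCollection) -> pd.DataFrame:
    """Matrix of |P_S n P_T| / |P_S| over ordered pathway pairs.

    Rows are the source pathway (the normalizer), so the matrix is asymmetric
    in general and has a unit diagonal.
    """
    names = p.names
    mat = np.zeros((len(names), len(names)))
    for i, s in enumerate(names):
        ps = p.members(s)
        for j, t in enumerate(names):
            mat[i, j] = len(ps & p.members(t)) / len(ps)
    return pd.DataFrame(mat, index=names, columns=names)


def influence_score(
    relax: RelaxationResult,
    p_s: Iterable[str],
    p_t: Iterable[str],
    k: int,
) -> float:
    """s_k for a relaxation result computed with source = P_S."""
    if k < 0:
        raise ValueError("k must be non-negative")
    ps, pt = frozenset(p_s), frozenset(p_t)
    overlap = ps & pt
    b_leq_k = relax.b_leq_k(k)
    denom = b_leq_k - overlap
    if not denom:
        return 0.0
    num = (b_leq_k & pt) - overlap
    return len(num) / len(denom)


def influence_profile(
    h: DirectedHypergraph,
    p: PathwayCollection,
    source: str,
    k_max: int,
    table: HeadVisitTable | None = None,
) -> pd.DataFrame:
    """Per-target, per-k influence scores from one source pathway.

    A single relaxation run from the source pathway's member set serves all
    targets and all k <= k_max.  The returned frame has one row per (target, k)
    with columns ``score`` and ``b_leq_k_size`` (the growing reach of the
    source, shared across targets at a given k).
    """
    ps = p.members(source)
    if table is None:
        table = precompute_head_visits(h)
    relax = b_relaxation_fast(h, ps, table)
    rows = []
    for target in p.names:
        if target == source:
            continue
        pt = p.members(target)
        for k in range(k_max + 1):
            rows.append(
                {
                    "source": source,
                    "target": target,
                    "k": k,
                    "score": influence_score(relax, ps, pt, k),
                    "b_leq_k_size": len(relax.b_leq_k(k)),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PermutationGraph:
    """Bipartite molecules-vs-membership-regions structure.

    Each molecule in the union of the pathways is linked (degree one) to the
    Venn region naming exactly the pathways containing it; only non-empty
    regions are materialized.  Shuffling molecule-to-region assignments leaves
    every region size — and therefore every pairwise overlap count — intact.
    """

    molecules: List[str]
    regions: List[FrozenSet[str]]  # region identity: the set of pathway names
    assignment: np.ndarray  # molecule index -> region index
    region_sizes: Dict[FrozenSet[str], int] = field(default_factory=dict)

    def to_collection(
        self, hypergraph: DirectedHypergraph | None = None
    ) -> PathwayCollection:
        pathways: Dict[str, Set[str]] = {}
        for mi, m in enumerate(self.molecules):
            for name in self.regions[self.assignment[mi]]:
                pathways.setdefault(name, set()).add(m)
        return PathwayCollection(pathways, hypergraph)


def build_permutation_graph(p: PathwayCollection) -> PermutationGraph:
    """Construct the molecules-vs-regions bipartite graph for a collection."""
    molecules = sorted(p.molecule_universe())
    region_of: Dict[str, FrozenSet[str]] = {}
    for m in molecules:
        region_of[m] = frozenset(name for name in p.names if m in p.members(name))
    regions = sorted(set(region_of.values()), key=sorted)
    region_index = {r: i for i, r in enumerate(regions)}
    assignment = np.array([region_index[region_of[m]] for m in molecules])
    sizes = {r: int(np.sum(assignment == i)) for i, r in enumerate(regions)}
    return PermutationGraph(molecules, regions, assignment, sizes)


def permute_memberships(
    pg: PermutationGraph,
    n_swaps: int,
    seed: int | np.random.Generator,
    hypergraph: DirectedHypergraph | None = None,
) -> PathwayCollection:
    """Shuffle memberships by degree-preserving edge swaps; return the
    resulting collection.

    Each proposal draws two molecules uniformly; if they sit in different
    regions their assignments are exchanged, otherwise the proposal is
    rejected (it would duplicate an existing edge) and still counts as an
    attempt.  Pathway sizes, all pairwise intersections, and the molecule
    universe are invariant by construction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    assignment = pg.assignment.tolist()  # list indexing is fastest for the swap loop
    n_mol = len(pg.molecules)
    if n_swaps > 0 and n_mol >= 2:
        pairs = rng.integers(0, n_mol, size=(n_swaps, 2)).tolist()
        for a, b in pairs:
            ra, rb = assignment[a], assignment[b]
            if ra != rb:
                assignment[a], assignment[b] = rb, ra
    shuffled = PermutationGraph(
        pg.molecules, pg.regions, np.asarray(assignment), pg.region_sizes
    )
    return shuffled.to_collection(hypergraph)


def permutation_significance(
    h: DirectedHypergraph,
    p: PathwayCollection,
    source: str,
    target: str,
    k: int,
    n_perm: int = 1000,
    n_swaps: int = 10_000,
    seed: int = 0,
    table: HeadVisitTable | None = None,
) -> InfluenceRecord:
    """Observed s_k and its permutation null for one pathway pair.

    Each permutation recomputes the relaxation from the permuted source
    member set; the hypergraph is unchanged, so all runs share one head-visit
    table.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if table is None:
        table = precompute_head_visits(h)
    ps, pt = p.members(source), p.members(target)
    observed = influence_score(b_relaxation_fast(h, ps, table), ps, pt, k)
    pg = build_permutation_graph(p)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = permute_memberships(pg, n_swaps, rng)
        qs, qt = perm.members(source), perm.members(target)
        src = frozenset(qs) & frozenset(h.nodes)
        if not src:
            score = 0.0
        else:
            score = influence_score(b_relaxation_fast(h, src, table), qs, qt, k)
        if score >= observed:
            n_ge += 1
    return InfluenceRecord(source, target, k, observed, n_perm, n_ge)
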