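"""Enrichment of scored functional interactions by connectivity category.

Given a table of scored protein-protein associations (STRING links dialect:
per-evidence-channel integer scores in [1, 1000]), each interacting pair is
placed into nested connectivity categories on the reaction hypergraph:

    B-connected  (dist 0)  subset of  B_<=k  subset of  bipartite-connected,

plus pathway-membership categories (both proteins in any pathway / in the same
pathway).  Score distributions across categories are compared with the
Kruskal-Wallis rank test: if stricter connectivity marks closer functional
relationships, stricter categories should carry higher scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import networkx as nx
import pandas as pd
from scipy import stats

from .hypergraph import DirectedHypergraph
from .influence import PathwayCollection
from .relaxation import HeadVisitTable, b_relaxation_fast, precompute_head_visits

__all__ = [
    "ScoredInteraction",
    "ScoredInteractionSet",
    "categorize_interactions",
    "compare_score_distributions",
    "DEFAULT_EXCLUDED_CHANNELS",
]

logger = logging.getLogger(__name__)

# Channels backed by evidence transferred via homology, plus the curated
# "database" channel (circular when the database under study feeds it), are
# excluded by default.
DEFAULT_EXCLUDED_CHANNELS = frozenset(
    {
        "database",
        "database_transferred",
        "experiments_transferred",
        "coexpression_transferred",
        "textmining_transferred",
        "homology",
    }
)


@dataclass(frozen=True)
class ScoredInteraction:
    protein_a: str
    protein_b: str
    channel: str
    score: int

    def __post_init__(self):
        if not (1 <= self.score <= 1000):
            raise ValueError(
                f"score {self.score} for ({self.protein_a}, {self.protein_b}) "
                "outside [1, 1000]"
            )


class ScoredInteractionSet:
    """Deduplicated scored interactions, keyed by unordered pair and channel.

    Duplicate unordered pairs within a channel keep the maximum score.
    """

    def __init__(self, records: Iterable[ScoredInteraction] = ()):
        self._records: Dict[Tuple[frozenset, str], ScoredInteraction] = {}
        for r in records:
            self.add(r)

    def add(self, rec: ScoredInteraction) -> None:
        key = (frozenset({rec.protein_a, rec.protein_b}), rec.channel)
        old = self._records.get(key)
        if old is None or rec.score > old.score:
            self._records[key] = rec

    @property
    def records(self) -> List[ScoredInteraction]:
        return sorted(
            self._records.values(),
            key=lambda r: (r.channel, r.protein_a, r.protein_b),
        )

    def channels(self) -> List[str]:
        return sorted({r.channel for r in self._records.values()})

    def __len__(self) -> int:
        return len(self._records)


def categorize_interactions(
    interactions: ScoredInteractionSet,
    h: DirectedHypergraph,
    pathways: PathwayCollection,
    bipartite: nx.DiGraph | None = None,
    k_thresholds: Sequence[int] = (3,),
    table: HeadVisitTable | None = None,
    direction: str = "either",
) -> pd.DataFrame:
    """Flag every interaction with its connectivity and pathway categories.

    A pair (u, v) is connected under a measure when u reaches v or v reaches u
    (``direction='either'``, the default) or only when both directions hold
    (``direction='both'``).  Connectivity is read off the B-relaxation
    distances between the two endpoints: distance 0 is B-connectivity, finite
    distance is bipartite-graph connectivity, and distance <= k fills the
    intermediate categories.  When a bipartite graph is supplied its BFS
    reachability is used for the bipartite flag instead (the two routes agree;
    passing it lets callers cross-check the equivalence).

    Interactions with an endpoint absent from the hypergraph are flagged
    ``out_of_universe`` and should be excluded from score distributions.
    """
    if direction not in ("either", "both"):
        raise ValueError("direction must be 'either' or 'both'")
    if table is None:
        table = precompute_head_visits(h)
    proteins = sorted(
        {r.protein_a for r in interactions.records}
        | {r.protein_b for r in interactions.records}
    )
    in_universe = [p for p in proteins if p in h.nodes]
    dist: Dict[str, Dict[str, float]] = {}
    for p in in_universe:
        dist[p] = b_relaxation_fast(h, {p}, table).dist

    bip_reach: Dict[str, set] | None = None
    if bipartite is not None:
        bip_reach = {p: set(nx.descendants(bipartite, p)) | {p} for p in in_universe}

    def pair_dist(u: str, v: str) -> float:
        duv, dvu = dist[u].get(v, math.inf), dist[v].get(u, math.inf)
        return min(duv, dvu) if direction == "either" else max(duv, dvu)

    rows = []
    for rec in interactions.records:
        u, v = rec.protein_a, rec.protein_b
        oou = u not in h.nodes or v not in h.nodes
        row = {
            "protein_a": u,
            "protein_b": v,
            "channel": rec.channel,
            "score": rec.score,
            "out_of_universe": oou,
        }
        names_u = {n for n in pathways.names if u in pathways.members(n)}
        names_v = {n for n in pathways.names if v in pathways.members(n)}
        row["in_any_pathway"] = bool(names_u) and bool(names_v)
        row["in_same_pathway"] = bool(names_u & names_v)
        if oou:
            row["b_connected"] = False
            row["bipartite_connected"] = False
            for k in k_thresholds:
                row[f"b_leq_{k}"] = False
        else:
            d = pair_dist(u, v)
            row["b_connected"] = d == 0
            if bip_reach is not None:
                fwd, bwd = v in bip_reach[u], u in bip_reach[v]
                row["bipartite_connected"] = (
                    (fwd or bwd) if direction == "either" else (fwd and bwd)
                )
            else:
                row["bipartite_connected"] = d < math.inf
            for k in k_thresholds:
                row[f"b_leq_{k}"] = d <= k
        rows.append(row)
    return pd.DataFrame(rows)


def compare_score_distributions(
    categorized: pd.DataFrame,
    categories: Sequence[str] | None = None,
) -> Tuple[pd.DataFrame, float, float]:
    """Per-category score summaries plus a Kruskal-Wallis test across them.

    ``categories`` default to every boolean flag column present.  Rows flagged
    out-of-universe are dropped first.  Returns (summary frame with n, median
    and quartiles per category, H statistic, p-value).  Empty categories are
    omitted with a warning; fewer than two non-empty categories is an error.
    """
    df = categorized[~categorized["out_of_universe"]]
    if categories is None:
        categories = [
            c
            for c in df.columns
            if df[c].dtype == bool and c != "out_of_universe"
        ]
    groups, summary_rows = [], []
    for cat in categories:
        scores = df.loc[df[cat], "score"].to_numpy()
        if len(scores) == 0:
            logger.warning("category %r is empty; omitted", cat)
            continue
        groups.append(scores)
        q1, med, q3 = (float(x) for x in pd.Series(scores).quantile([0.25, 0.5, 0.75]))
        summary_rows.append(
            {"category": cat, "n": len(scores), "q1": q1, "median": med, "q3": q3}
        )
    if len(groups) < 2:
        raise ValueError("need at least two non-empty categories to compare")
    try:
        h_stat, p = stats.kruskal(*groups)
    except ValueError:
        # all values identical across all groups: no separation by definition
        h_stat, p = 0.0, 1.0
    return pd.DataFrame(summary_rows), float(h_stat), float(p)
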