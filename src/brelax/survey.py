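"""Whole-network connectivity surveys.

Two summaries of how connected a representation is:

- a pooled pair-distance histogram: for an all-pairs distance matrix, how many
  ordered node pairs sit at each finite distance and how many are unreachable
  (self-pairs excluded);
- a per-source relaxation heatmap: |B_<=k| for every source node and every
  k up to a cap, whose first column is the plain B-connected reach and whose
  limiting column equals bipartite-graph reachability counts.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable

import numpy as np
import pandas as pd

from .hypergraph import DirectedHypergraph
from .relaxation import HeadVisitTable, b_relaxation_fast, precompute_head_visits

__all__ = ["pair_distance_histogram", "relaxation_heatmap"]


def pair_distance_histogram(dist: pd.DataFrame) -> Dict[object, int]:
    """Counts of ordered node pairs at each finite distance, plus unreachable.

    ``dist`` is a square distance matrix (rows = sources); the diagonal is
    excluded.  Returns a dict mapping each finite distance to its pair count,
    with key ``'unreachable'`` for infinite entries.  Counts sum to n*(n-1).
    """
    if dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    a = dist.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, np.nan)
    flat = a[~np.isnan(a)]
    out: Dict[object, int] = {}
    finite = flat[np.isfinite(flat)]
    vals, counts = np.unique(finite.astype(int), return_counts=True)
    for v, c in zip(vals, counts):
        out[int(v)] = int(c)
    out["unreachable"] = int(np.sum(~np.isfinite(flat)))
    return out


def relaxation_heatmap(
    h: DirectedHypergraph,
    k_max: int = 49,
    table: HeadVisitTable | None = None,
    sources: Iterable[str] | None = None,
    sort_by_reach: bool = False,
) -> pd.DataFrame:
    """|B_<=k| per source node per k in [0, k_max].

    Each row is a source node; entry (v, k) counts the nodes whose
    B-relaxation distance from {v} is at most k, source included.  Rows are
    non-decreasing in k; column 0 is the B-connected reach, and once k exceeds
    every finite distance the row equals the source's bipartite-reachable
    count.  ``sort_by_reach`` orders rows by the final column (survey-figure
    convention).
    """
    if table is None:
        table = precompute_head_visits(h)
    src_nodes = sorted(h.nodes) if sources is None else sorted(sources)
    rows = np.zeros((len(src_nodes), k_max + 1), dtype=int)
    for i, v in enumerate(src_nodes):
        res = b_relaxation_fast(h, {v}, table)
        ds = np.sort(
            np.array([d for d in res.dist.values() if d < math.inf], dtype=int)
        )
        # entry k = number of finite distances <= k
        rows[i] = np.searchsorted(ds, np.arange(k_max + 1), side="right")
    df = pd.DataFrame(rows, index=src_nodes, columns=range(k_max + 1))
    if sort_by_reach:
        df = df.loc[df[k_max].sort_values(kind="stable").index]
    return df
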