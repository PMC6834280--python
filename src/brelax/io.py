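"""Readers and writers for the package's plain-text formats.

- hyperedge TSV: three tab-separated columns (hyperedge id, tail node ids
  joined by ';', head node ids joined by ';'); '#' lines are comments;
- node-attribute TSV: node id, entity type, display name;
- GMT pathway sets: name, description, then tab-separated member ids;
- SIF: three tab-separated columns (source, relation, target);
- scored interactions, STRING links dialect: whitespace-delimited with a
  header row naming the two protein columns and one column per evidence
  channel;
- blacklist / node list: one node id per line.

All writers emit sorted keys so repeated runs are byte-identical, and prefix
output with '#'-comment provenance headers.  ';' is reserved as the in-cell
list separator and therefore forbidden in node ids.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

from .benchmark import ScoredInteraction, ScoredInteractionSet
from .hypergraph import DirectedHypergraph, NodeAttributes
from .influence import PathwayCollection

__all__ = [
    "read_hypergraph",
    "write_hypergraph",
    "read_node_attributes",
    "write_node_attributes",
    "read_pathways_gmt",
    "write_pathways_gmt",
    "read_sif",
    "write_sif",
    "read_node_list",
    "read_scored_interactions",
    "write_distances",
]

logger = logging.getLogger(__name__)

LIST_SEP = ";"


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


def _data_lines(path: str | Path) -> Iterable[Tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def _check_node_id(node: str, path, lineno: int) -> str:
    if LIST_SEP in node:
        raise FormatError(f"{path}:{lineno}: node id {node!r} contains {LIST_SEP!r}")
    return node


def read_hypergraph(
    path: str | Path, attrs_path: str | Path | None = None
) -> Tuple[DirectedHypergraph, NodeAttributes]:
    """Load a hyperedge TSV (and optional node-attribute TSV)."""
    h = DirectedHypergraph()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
        eid, tail_s, head_s = fields
        tail = [_check_node_id(v, path, lineno) for v in tail_s.split(LIST_SEP) if v]
        head = [_check_node_id(v, path, lineno) for v in head_s.split(LIST_SEP) if v]
        if not tail or not head:
            raise FormatError(f"{path}:{lineno}: hyperedge {eid!r} has empty tail or head")
        try:
            h.add_hyperedge(eid, tail, head)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    # isolated nodes are carried on '#node' directive lines
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("#node\t"):
                h.add_node(raw.rstrip("\n").split("\t", 1)[1])
    attrs = read_node_attributes(attrs_path) if attrs_path else NodeAttributes()
    return h, attrs


def write_hypergraph(
    h: DirectedHypergraph, path: str | Path, header: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("# hyperedge_id\ttail\thead\n")
        for eid in sorted(h.hyperedges):
            tail, head = h.hyperedges[eid]
            fh.write(
                f"{eid}\t{LIST_SEP.join(sorted(tail))}\t{LIST_SEP.join(sorted(head))}\n"
            )
        used = set().union(
            *(t | hd for t, hd in h.hyperedges.values()), frozenset()
        ) if h.hyperedges else set()
        for v in sorted(h.nodes - used):
            fh.write(f"#node\t{v}\n")


def read_node_attributes(path: str | Path) -> NodeAttributes:
    attrs = NodeAttributes()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected >= 2 columns")
        node, etype = fields[0], fields[1]
        name = fields[2] if len(fields) > 2 else node
        try:
            attrs.set(node, etype, name)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return attrs


def write_node_attributes(
    attrs: NodeAttributes, path: str | Path, header: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("# node_id\tentity_type\tdisplay_name\n")
        for node in sorted(attrs.entity_type):
            fh.write(
                f"{node}\t{attrs.entity_type[node]}\t{attrs.display_name[node]}\n"
            )


def read_pathways_gmt(
    path: str | Path, hypergraph: DirectedHypergraph | None = None
) -> PathwayCollection:
    """Load GMT pathway sets (name, description, members...).

    Duplicate members deduplicate silently; a line with fewer than three
    columns, or a pathway with no members, is an error.  When a hypergraph is
    supplied, members are restricted to its node set.
    """
    pathways: Dict[str, List[str]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT needs name, description and >= 1 member"
            )
        name, _desc, *members = fields
        members = [m for m in members if m]
        if not members:
            raise FormatError(f"{path}:{lineno}: pathway {name!r} has no members")
        if name in pathways:
            raise FormatError(f"{path}:{lineno}: duplicate pathway {name!r}")
        pathways[name] = members
    return PathwayCollection(pathways, hypergraph)


def write_pathways_gmt(p: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in p.names:
            fh.write("\t".join([name, name] + sorted(p.members(name))) + "\n")


def read_sif(path: str | Path) -> List[Tuple[str, str, str]]:
    records = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 3:
            raise FormatError(f"{path}:{lineno}: SIF needs exactly 3 columns")
        records.append(tuple(fields))
    return records


def write_sif(edges: Iterable[Tuple[str, str]], path: str | Path, relation: str = "edge") -> None:
    with open(path, "w") as fh:
        for src, dst in sorted(edges):
            fh.write(f"{src}\t{relation}\t{dst}\n")


def read_node_list(path: str | Path) -> List[str]:
    return [line.strip() for _, line in _data_lines(path)]


def read_scored_interactions(
    path: str | Path, id_map_path: str | Path | None = None
) -> ScoredInteractionSet:
    """Load a STRING-links-style scored interaction table.

    Whitespace-delimited with a header row: first two columns name the
    proteins, the rest are evidence channels with integer scores in [1, 1000]
    (zero means "no evidence in this channel" and yields no record).  An
    optional two-column id map is applied to both proteins; records with an
    unmappable id are excluded and counted in a log message.
    """
    id_map: Dict[str, str] | None = None
    if id_map_path:
        id_map = {}
        for lineno, line in _data_lines(id_map_path):
            fields = line.split()
            if len(fields) != 2:
                raise FormatError(f"{id_map_path}:{lineno}: expected 2 columns")
            id_map[fields[0]] = fields[1]

    out = ScoredInteractionSet()
    header: List[str] | None = None
    unmapped = 0
    for lineno, line in _data_lines(path):
        fields = line.split()
        if header is None:
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: header needs >= 3 columns")
            header = fields
            continue
        if len(fields) != len(header):
            raise FormatError(f"{path}:{lineno}: expected {len(header)} columns")
        a, b = fields[0], fields[1]
        if id_map is not None:
            if a not in id_map or b not in id_map:
                unmapped += 1
                continue
            a, b = id_map[a], id_map[b]
        for channel, value in zip(header[2:], fields[2:]):
            score = int(value)
            if score == 0:
                continue
            try:
                out.add(ScoredInteraction(a, b, channel, score))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if unmapped:
        logger.info("excluded %d interactions with unmappable ids", unmapped)
    return out


def write_distances(
    dist: Dict[str, float], path: str | Path, header: Sequence[str] = ()
) -> None:
    """Write node -> distance as TSV; infinity serializes as 'inf'."""
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("# node_id\tb_relaxation_distance\n")
        for node in sorted(dist):
            d = dist[node]
            fh.write(f"{node}\t{'inf' if math.isinf(d) else int(d)}\n")
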