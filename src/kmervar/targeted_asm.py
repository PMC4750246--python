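"""Starter-anchored targeted assembly of the graph neighborhood.

A *starter* is a user-supplied sequence of interest.  After validating
that enough of its k-mer windows are solid in the read data, the
starter is extended in both directions.  Two output shapes are
offered: a linear extension that is cut as soon as the assembly faces
two choices, and a JSON neighborhood graph of compacted unitig nodes
in which polymorphisms downstream of the starter appear as parallel
nodes ("bubbles"), each annotated with its mean k-mer coverage in
every read set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dbg import DeBruijnGraph
from .kmer_index import (
    CountTable,
    SolidSet,
    canonical_kmer_array,
    decode_kmer,
    encode_kmer,
    revcomp_int,
    reverse_complement,
)
from .seq_io import SequenceRecord

__all__ = [
    "Starter",
    "NeighborhoodGraph",
    "GraphNode",
    "validate_starter",
    "make_starter",
    "extend_linear",
    "build_neighborhood_graph",
    "write_graph_json",
    "read_graph_json",
    "validate_graph_doc",
]

_BASES = "ACGT"


@dataclass
class Starter:
    identifier: str
    sequence: str
    solid_fraction: float = 0.0


def make_starter(record: SequenceRecord, solid: SolidSet) -> Starter:
    """Wrap a record, computing the fraction of its windows that are solid."""
    k = solid.k
    if len(record.sequence) < k:
        raise ValueError(
            f"starter {record.identifier!r} shorter than k={k}"
        )
    kmers = canonical_kmer_array(record.sequence, k)
    n_windows = len(record.sequence) - k + 1
    if kmers.size == 0:
        frac = 0.0
    else:
        frac = float(solid.contains_canonical_array(kmers).sum()) / n_windows
    return Starter(record.identifier, record.sequence, frac)


def validate_starter(
    starter: Starter, solid: SolidSet, min_fraction: float = 0.7
) -> bool:
    """Accept a starter iff enough of its windows are solid in the reads."""
    if len(starter.sequence) < solid.k:
        raise ValueError(f"starter {starter.identifier!r} shorter than k={solid.k}")
    return starter.solid_fraction >= min_fraction


def extend_linear(
    g: DeBruijnGraph, starter: Starter, max_len: int = 10_000
) -> tuple[str, str]:
    """(left, right) extension bases; each side is cut at the first fork.

    The walk stops at a dead end, at a node offering two or more
    choices, on a loop, or at ``max_len`` bases.  A terminal k-mer that
    is not solid yields an empty extension on that side (with a
    warning), since the graph offers no anchor there.
    """
    k = g.spec.k
    left = right = ""
    tail = starter.sequence[-k:]
    head = starter.sequence[:k]
    if max_len > 0:
        if tail in g:
            right = g.extend_unitig(tail, "right", max_len, require_unique_pred=False)
        else:
            warnings.warn(
                f"starter {starter.identifier!r}: right terminal k-mer not solid"
            )
        if head in g:
            left = g.extend_unitig(head, "left", max_len, require_unique_pred=False)
        else:
            warnings.warn(
                f"starter {starter.identifier!r}: left terminal k-mer not solid"
            )
    return left, right


@dataclass
class GraphNode:
    node_id: int
    seq: str
    cov: list[float]
    is_starter: bool = False


@dataclass
class NeighborhoodGraph:
    k: int
    starter_id: int
    nodes: list[GraphNode] = field(default_factory=list)
    edges: list[tuple[int, int]] = field(default_factory=list)


def _mean_coverage(seq: str, tables: list[tuple[str, CountTable]], k: int) -> list[float]:
    kmers = canonical_kmer_array(seq, k)
    out = []
    for _name, table in tables:
        if kmers.size == 0:
            out.append(0.0)
        else:
            out.append(float(table.get_many(kmers).mean()))
    return out


def build_neighborhood_graph(
    g: DeBruijnGraph,
    starter: Starter,
    tables: list[tuple[str, CountTable]],
    max_nodes: int = 200,
    max_depth: int = 5,
) -> NeighborhoodGraph:
    """Breadth-first compacted-unitig exploration around the starter.

    The starter node carries the starter plus its fork-free linear
    extensions.  From each of its ends, branching successors open new
    unitig nodes (standard both-sides-unique compaction), explored
    breadth-first up to ``max_depth`` branch levels or ``max_nodes``
    nodes.  Re-reaching a unitig adds an edge, not a node, so the two
    allele branches of a bubble reconverge on a shared node.  Node ids
    follow exploration order with successors sorted by base, making the
    graph deterministic.

    Each node carries, per read set, the mean count of its k-mer
    windows in that set's table.
    """
    k = g.spec.k
    left, right = extend_linear(g, starter)
    start_seq = left + starter.sequence + right
    graph = NeighborhoodGraph(k=k, starter_id=0)
    graph.nodes.append(
        GraphNode(0, start_seq, _mean_coverage(start_seq, tables, k), True)
    )
    edges: set[tuple[int, int]] = set()

    # exploration frontier: (parent id, oriented start k-mer int, side)
    # side +1 explores rightward of the stored orientation, -1 leftward
    # (leftward nodes are built on the reverse strand, then stored
    # reverse-complemented with the edge pointing back at the parent).
    memo: dict[tuple[int, int], int] = {}

    def unitig_from(x: int) -> tuple[str, list[int]]:
        """Unitig sequence starting at oriented k-mer x, plus its successors."""
        ext = g._extend_right_int(x, 10_000, True)
        seq = decode_kmer(x, k) + ext
        last = encode_kmer(seq[-k:])
        return seq, g.successors_int(last)

    frontier: list[tuple[int, int, int]] = []
    if start_seq[-k:] in g:
        for s in g.successors_int(encode_kmer(start_seq[-k:])):
            frontier.append((0, s, +1))
    if start_seq[:k] in g:
        head_rc = revcomp_int(encode_kmer(start_seq[:k]), k)
        for s in g.successors_int(head_rc):
            frontier.append((0, s, -1))

    depth = 0
    while frontier and depth < max_depth and len(graph.nodes) < max_nodes:
        next_frontier: list[tuple[int, int, int]] = []
        for parent, x, side in frontier:
            if len(graph.nodes) >= max_nodes:
                break
            key = (x, side)
            if key in memo:
                nid = memo[key]
            else:
                seq, succ = unitig_from(x)
                nid = len(graph.nodes)
                stored = seq if side > 0 else reverse_complement(seq)
                graph.nodes.append(
                    GraphNode(nid, stored, _mean_coverage(stored, tables, k))
                )
                memo[key] = nid
                for s in succ:
                    next_frontier.append((nid, s, side))
            if side > 0:
                edges.add((parent, nid))
            else:
                edges.add((nid, parent))
        frontier = next_frontier
        depth += 1

    graph.edges = sorted(edges)
    return graph


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def write_graph_json(graph: NeighborhoodGraph, path: str) -> None:
    """Write the neighborhood graph in the documented JSON schema."""
    doc = {
        "k": graph.k,
        "starter": graph.starter_id,
        "nodes": [
            {
                "id": n.node_id,
                "seq": n.seq,
                "cov": [round(c, 4) for c in n.cov],
                "is_starter": n.is_starter,
            }
            for n in graph.nodes
        ],
        "edges": [{"from": a, "to": b} for a, b in graph.edges],
    }
    with open(path, "w") as out:
        json.dump(doc, out, indent=1)
        out.write("\n")


def read_graph_json(path: str) -> NeighborhoodGraph:
    with open(path) as fh:
        doc = json.load(fh)
    validate_graph_doc(doc)
    graph = NeighborhoodGraph(k=doc["k"], starter_id=doc["starter"])
    for n in doc["nodes"]:
        graph.nodes.append(GraphNode(n["id"], n["seq"], n["cov"], n["is_starter"]))
    graph.edges = [(e["from"], e["to"]) for e in doc["edges"]]
    return graph


def validate_graph_doc(doc: dict) -> None:
    """Check a JSON document against the shipped neighborhood-graph schema."""
    if not isinstance(doc, dict):
        raise ValueError("graph document must be a JSON object")
    for key in ("k", "starter", "nodes", "edges"):
        if key not in doc:
            raise ValueError(f"graph document missing key {key!r}")
    if not isinstance(doc["k"], int) or not isinstance(doc["starter"], int):
        raise ValueError("'k' and 'starter' must be integers")
    ids = set()
    n_starters = 0
    for n in doc["nodes"]:
        for key, typ in (("id", int), ("seq", str), ("cov", list), ("is_starter", bool)):
            if key not in n or not isinstance(n[key], typ):
                raise ValueError(f"node missing or mistyped field {key!r}")
        if not all(isinstance(c, (int, float)) for c in n["cov"]):
            raise ValueError("node 'cov' must be a list of numbers")
        ids.add(n["id"])
        n_starters += n["is_starter"]
    if n_starters != 1:
        raise ValueError(f"exactly one starter node required, found {n_starters}")
    node_by_id = {n["id"]: n for n in doc["nodes"]}
    k = doc["k"]
    for e in doc["edges"]:
        if set(e) != {"from", "to"} or e["from"] not in ids or e["to"] not in ids:
            raise ValueError(f"edge {e!r} malformed or dangling")
        sa = node_by_id[e["from"]]["seq"]
        sb = node_by_id[e["to"]]["seq"]
        if sa[-(k - 1) :] != sb[: k - 1]:
            raise ValueError(
                f"edge {e['from']}->{e['to']} endpoints do not overlap by k-1"
            )
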