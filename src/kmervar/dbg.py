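"""Implicit de Bruijn graph over solid canonical k-mers.

Nodes are the solid canonical k-mers; arcs are the exact (k-1)-overlaps
between them.  The graph is never materialized: the successors of a
node are found by appending each of the four bases and asking the
membership structure whether the canonical form of the candidate is
solid (at most four queries per direction).  Traversal operates on
*oriented* k-mers while membership is strand-neutral, which realizes
the bidirected graph induced by double-stranded reads without doubling
storage.

When a bloom filter is attached, membership queries hit it first and
positives are confirmed in the exact solid set, so graph semantics stay
exact while most absent candidates are rejected by the filter alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kmer_index import (
    BloomFilter,
    KmerSpec,
    SolidSet,
    canonical_int,
    decode_kmer,
    encode_kmer,
)

__all__ = ["DeBruijnGraph", "build_graph"]

_BASES = "ACGT"


@dataclass
class DeBruijnGraph:
    spec: KmerSpec
    solid: SolidSet
    bloom: BloomFilter | None = None

    def __post_init__(self) -> None:
        k = self.spec.k
        if k != self.solid.k:
            raise ValueError("spec.k and solid.k disagree")
        self._mask = (1 << (2 * k)) - 1

    # -- integer-level membership and neighbors (hot path) -----------------

    def has_oriented(self, x: int) -> bool:
        """Is the canonical form of oriented packed k-mer ``x`` solid?"""
        if self.bloom is not None:
            c = canonical_int(x, self.spec.k)
            if not self.bloom.query_array(np.array([c], dtype=np.uint64))[0]:
                return False
            return c in self.solid._canon
        return self.solid.contains_oriented_int(x)

    def successors_int(self, x: int) -> list[int]:
        out = []
        base = (x << 2) & self._mask
        for b in range(4):
            y = base | b
            if self.has_oriented(y):
                out.append(y)
        return out

    def predecessors_int(self, x: int) -> list[int]:
        out = []
        k = self.spec.k
        tail = x >> 2
        for b in range(4):
            y = (b << (2 * (k - 1))) | tail
            if self.has_oriented(y):
                out.append(y)
        return out

    # -- string-level API ---------------------------------------------------

    def __contains__(self, kmer: str) -> bool:
        return self.has_oriented(encode_kmer(kmer))

    def successors(self, node: str) -> list[str]:
        """Oriented k-mers ``node[1:] + b`` whose canonical form is solid."""
        k = self.spec.k
        if len(node) != k:
            raise ValueError(f"node length {len(node)} != k={k}")
        return [decode_kmer(y, k) for y in self.successors_int(encode_kmer(node))]

    def predecessors(self, node: str) -> list[str]:
        """Oriented k-mers ``b + node[:-1]`` whose canonical form is solid."""
        k = self.spec.k
        if len(node) != k:
            raise ValueError(f"node length {len(node)} != k={k}")
        return [decode_kmer(y, k) for y in self.predecessors_int(encode_kmer(node))]

    # -- unitig extension ---------------------------------------------------

    def _extend_right_int(
        self, start: int, max_len: int, require_unique_pred: bool
    ) -> str:
        """Walk right from ``start`` while the path is unambiguous.

        Stops at a branch (>1 successor), a dead end, after ``max_len``
        bases, on revisiting a node (loop guard) or — unless
        ``require_unique_pred`` is off — when the next node has more
        than one predecessor (the both-sides-unique unitig rule, which
        prevents chimeras at bubble entrances).
        """
        ext: list[str] = []
        visited = {start}
        cur = start
        while len(ext) < max_len:
            succ = self.successors_int(cur)
            if len(succ) != 1:
                break
            nxt = succ[0]
            if require_unique_pred and len(self.predecessors_int(nxt)) != 1:
                break
            if nxt in visited:
                break
            ext.append(_BASES[nxt & 3])
            visited.add(nxt)
            cur = nxt
        return "".join(ext)

    def extend_unitig(
        self,
        start: str,
        direction: str = "right",
        max_len: int = 10_000,
        require_unique_pred: bool = True,
    ) -> str:
        """Unambiguous extension bases beyond ``start`` (start excluded).

        ``direction`` is ``"right"`` or ``"left"``; a left extension is
        returned in genomic order (it is the bases to prepend).
        """
        from .kmer_index import revcomp_int, reverse_complement

        k = self.spec.k
        if len(start) != k:
            raise ValueError(f"start length {len(start)} != k={k}")
        x = encode_kmer(start)
        if not self.has_oriented(x):
            raise ValueError(f"start k-mer {start!r} is not solid")
        if direction == "right":
            return self._extend_right_int(x, max_len, require_unique_pred)
        if direction == "left":
            ext = self._extend_right_int(revcomp_int(x, k), max_len, require_unique_pred)
            return reverse_complement(ext) if ext else ""
        raise ValueError(f"direction must be 'left' or 'right', got {direction!r}")


def build_graph(
    solid: SolidSet, bloom: BloomFilter | None = None
) -> DeBruijnGraph:
    return DeBruijnGraph(KmerSpec(solid.k), solid, bloom)
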