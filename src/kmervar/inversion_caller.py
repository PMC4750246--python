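"""Inversion-breakpoint detection from the de Bruijn graph.

A segment I is an inversion variant between two genomes when one
genome contains aIb and the other aI'b (I' the reverse complement),
for flanking k-mers a and b.  Writing u and v for the first and last
k-mers of I, the data then contain the four breakpoint words au, vb,
av' and u'b (each of length 2k), which join a, u, v and b in a
pseudo-cycle of two k-forks in the graph.  The caller searches for
that motif directly; the inverted segment itself is not reconstructed
(the motif does not determine it uniquely).

Repeated and palindromic sequence can produce the same motif without
any inversion.  As a guard, candidate (u, v) pairs whose u and v' are
locally similar (Hamming distance below ``min_fork_distance``) are
dropped; the exactly-palindromic case u = v' is flagged when the guard
is disabled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator

from .dbg import DeBruijnGraph
from .kmer_index import canonical_int, decode_kmer, encode_kmer, reverse_complement
from .seq_io import SequenceRecord, read_sequences, write_fasta

__all__ = [
    "InversionEvent",
    "find_inversions",
    "canonicalize_event",
    "write_inversions",
    "parse_inversions_fasta",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class InversionEvent:
    """Four k-mers (a, u, v, b) naming an inversion's breakpoint motif."""

    a: str
    u: str
    v: str
    b: str
    event_id: int | None = None

    @property
    def k(self) -> int:
        return len(self.a)

    @property
    def palindromic(self) -> bool:
        # u = v' in any orbit member; under the dual role-exchange the
        # same degeneracy reads b = a'
        return self.u == reverse_complement(self.v) or self.b == reverse_complement(self.a)

    def breakpoints(self) -> dict[str, str]:
        """The four 2k breakpoint words keyed au, vb, avp, upb."""
        return {
            "au": self.a + self.u,
            "vb": self.v + self.b,
            "avp": self.a + reverse_complement(self.v),
            "upb": reverse_complement(self.u) + self.b,
        }

    def serialized(self) -> str:
        return f"{self.a}|{self.u}|{self.v}|{self.b}"


def canonicalize_event(a: str, u: str, v: str, b: str) -> InversionEvent:
    """Smallest of the eight equivalent descriptions of one motif.

    The four breakpoint words, taken up to reverse complement, are
    invariant under (i) swapping the roles of (u, v) with (v', u'),
    (ii) reverse-complementing the whole locus, and (iii) the "dual"
    reading that exchanges flanks with segment terminals,
    (a,u,v,b) -> (u',a',b',v').  These generate an orbit of eight
    tuples; the representative is the orbit member with the
    lexicographically smallest "a|u|v|b" serialization.  Two events
    with the same breakpoint evidence therefore always canonicalize
    identically.
    """
    rc = reverse_complement
    orbit = [
        (a, u, v, b),
        (a, rc(v), rc(u), b),
        (rc(b), rc(v), rc(u), rc(a)),
        (rc(b), u, v, rc(a)),
        (rc(u), rc(a), rc(b), rc(v)),
        (rc(u), b, a, rc(v)),
        (v, b, a, u),
        (v, rc(a), rc(b), u),
    ]
    best = min(orbit, key=lambda t: "|".join(t))
    return InversionEvent(*best)


def _right_extension_ends(
    g: DeBruijnGraph, start: int, max_paths: int
) -> set[int] | None:
    """End k-mers of all solid right-extensions of length exactly k.

    Walks k steps from ``start``; every intermediate window must be
    solid.  Returns None when the number of partial paths exceeds
    ``max_paths`` (repeat-induced blowup: the start is abandoned).
    """
    k = g.spec.k
    mask = g._mask
    frontier = {start}
    for _ in range(k):
        nxt: set[int] = set()
        for x in frontier:
            base = (x << 2) & mask
            for b in range(4):
                y = base | b
                if g.has_oriented(y):
                    nxt.add(y)
        if len(nxt) > max_paths:
            return None
        if not nxt:
            return set()
        frontier = nxt
    return frontier


def _hamming_int(x: int, y: int, k: int) -> int:
    z = x ^ y
    d = 0
    for _ in range(k):
        if z & 3:
            d += 1
        z >>= 2
    return d


def find_inversions(
    g: DeBruijnGraph, max_paths: int = 100, min_fork_distance: int = 3
) -> list[InversionEvent]:
    """Enumerate canonical inversion breakpoint motifs in the graph.

    For every solid oriented k-mer ``a`` with at least two successors
    (a k-fork), all solid right-extensions of length k are enumerated
    (abandoning ``a`` if partial paths exceed ``max_paths``).  Each
    reached k-mer is both a candidate u (via the word au) and, reverse
    complemented, a candidate v (via av').  Pairs passing the
    Hamming(u, v') >= ``min_fork_distance`` guard are completed by
    searching k-mers b whose words vb and u'b are fully solid, i.e.
    the intersection of the extension ends of v and of u'.
    """
    k = g.spec.k
    rc = reverse_complement
    found: dict[str, InversionEvent] = {}
    ext_cache: dict[int, set[int] | None] = {}

    def ext_ends(x: int) -> set[int] | None:
        if x not in ext_cache:
            ext_cache[x] = _right_extension_ends(g, x, max_paths)
        return ext_cache[x]

    from .kmer_index import revcomp_int, revcomp_int_array
    import numpy as np

    arr = g.solid.members_array
    oriented = np.unique(
        np.concatenate([arr, revcomp_int_array(arr, k)])
    ) if arr.size else np.empty(0, dtype="uint64")

    # a genuine inversion makes `a` a k-fork (branches towards u and v');
    # the degenerate palindromic motif u = v' does not branch at all, so
    # when the guard is disabled the seed requirement drops to one successor
    min_succ = 2 if min_fork_distance > 0 else 1

    for a_int in oriented.tolist():
        a_int = int(a_int)
        if len(g.successors_int(a_int)) < min_succ:
            continue
        ends = ext_ends(a_int)
        if not ends:
            continue
        ends_list = sorted(ends)
        for u_int in ends_list:
            for w_int in ends_list:  # w realizes av'; v = rc(w)
                dist = _hamming_int(u_int, w_int, k)
                if dist < min_fork_distance:
                    continue
                v_int = revcomp_int(w_int, k)
                b1 = ext_ends(v_int)
                if b1 is None or not b1:
                    continue
                b2 = ext_ends(revcomp_int(u_int, k))
                if b2 is None:
                    continue
                a_canon = canonical_int(a_int, k)
                for b_int in sorted(b1 & b2):
                    # the motif joins FOUR k-mers in a pseudo-cycle; b
                    # canonically equal to a degenerates it — such
                    # candidates are strand-crossing chimeras that arise
                    # whenever a segment and its reverse complement both
                    # occur in the pooled data
                    if canonical_int(b_int, k) == a_canon:
                        continue
                    ev = canonicalize_event(
                        decode_kmer(a_int, k),
                        decode_kmer(u_int, k),
                        decode_kmer(v_int, k),
                        decode_kmer(b_int, k),
                    )
                    found.setdefault(ev.serialized(), ev)

    events = [found[key] for key in sorted(found)]
    return [
        InversionEvent(e.a, e.u, e.v, e.b, event_id=i)
        for i, e in enumerate(events)
    ]


# ---------------------------------------------------------------------------
# FASTA emission: four records per event, one per breakpoint word
# ---------------------------------------------------------------------------

def write_inversions(
    events: list[InversionEvent], path: str, header_lines: list[str] | None = None
) -> int:
    records = []
    for ev in events:
        flag = int(ev.palindromic)
        for label, word in ev.breakpoints().items():
            records.append(
                SequenceRecord(
                    f"INV_{ev.event_id}|{label}|palindromic={flag}", word
                )
            )
    write_fasta(records, path, line_width=0, header_lines=header_lines or [])
    return len(records) // 4


_INV_RE = re.compile(r"^INV_(\d+)\|(au|vb|avp|upb)\|palindromic=([01])$")


def parse_inversions_fasta(path: str) -> list[InversionEvent]:
    """Inverse of :func:`write_inversions`."""
    words: dict[int, dict[str, str]] = {}
    for rec in read_sequences(path):
        m = _INV_RE.match(rec.identifier)
        if not m:
            raise ValueError(f"{path}: malformed inversion record {rec.identifier!r}")
        words.setdefault(int(m.group(1)), {})[m.group(2)] = rec.sequence
    events = []
    for eid in sorted(words):
        w = words[eid]
        if set(w) != {"au", "vb", "avp", "upb"}:
            raise ValueError(f"{path}: event {eid} is missing breakpoint words")
        k = len(w["au"]) // 2
        events.append(
            InversionEvent(
                a=w["au"][:k], u=w["au"][k:], v=w["vb"][:k], b=w["vb"][k:],
                event_id=eid,
            )
        )
    return events
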