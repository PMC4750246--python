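"""Isolated-SNP bubble detection in the de Bruijn graph.

An isolated SNP — a substitution with no other polymorphism within its
(2k-1)-window — generates a *bubble*: a pair of paths of k vertices
each, spelling two sequences of length 2k-1 that differ at exactly the
center position.  Detection seeds on pairs of solid oriented k-mers
identical except at their last base (the left fork of the bubble) and
extends both paths simultaneously for k-1 steps, requiring every window
of both paths to be solid.

In ``strict`` mode (the default, conservative) each simultaneous step
must admit exactly one base keeping both paths solid; candidates whose
extension branches are discarded.  ``relaxed`` mode enumerates every
admissible completion instead.  Output is deduplicated to a
reverse-complement-canonical representative, so running on
reverse-complemented reads yields the identical bubble set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .dbg import DeBruijnGraph
from .kmer_index import (
    canonical_int,
    decode_kmer,
    encode_kmer,
    revcomp_int_array,
    reverse_complement,
)
from .seq_io import SequenceRecord, read_sequences, write_fasta

__all__ = [
    "SnpBubble",
    "find_snp_bubbles",
    "extend_flanks",
    "write_bubbles_fasta",
    "parse_bubbles_fasta",
    "canonical_path_pair",
]

_BASES = "ACGT"


@dataclass
class SnpBubble:
    """Two (2k-1)-length allele paths differing only at the center.

    ``path_a < path_b`` lexicographically; the pair is its own
    reverse-complement-canonical representative.  Flanking contigs are
    shared by both alleles.  ``counts``/``phi`` are attached by the
    quantification stage.
    """

    path_a: str
    path_b: str
    left_contig: str = ""
    right_contig: str = ""
    bubble_id: int | None = None
    counts: "object | None" = None
    phi: float | None = None

    @property
    def k(self) -> int:
        return (len(self.path_a) + 1) // 2

    @property
    def center(self) -> int:
        return self.k - 1

    def flanked(self, which: str) -> str:
        path = self.path_a if which == "A" else self.path_b
        return self.left_contig + path + self.right_contig

    @property
    def flanked_center(self) -> int:
        return len(self.left_contig) + self.center

    def __post_init__(self) -> None:
        if len(self.path_a) != len(self.path_b):
            raise ValueError("allele paths differ in length")
        diffs = [i for i, (a, b) in enumerate(zip(self.path_a, self.path_b)) if a != b]
        if diffs != [self.center]:
            raise ValueError(
                f"allele paths must differ exactly at the center "
                f"(index {self.center}), differ at {diffs}"
            )


def canonical_path_pair(pa: str, pb: str) -> tuple[str, str]:
    """Reverse-complement-canonical, sorted representative of a path pair."""
    fwd = tuple(sorted((pa, pb)))
    rev = tuple(sorted((reverse_complement(pa), reverse_complement(pb))))
    return min(fwd, rev)


def _path_windows_solid(g: DeBruijnGraph, x: int, bases: str) -> bool:
    """All windows of decode(x)+bases solid, stepping one base at a time."""
    mask = g._mask
    for ch in bases:
        x = ((x << 2) & mask) | _BASES.index(ch)
        if not g.has_oriented(x):
            return False
    return True


def _seed_pairs(g: DeBruijnGraph) -> Iterator[tuple[int, int]]:
    """Pairs of solid oriented k-mers identical except at the last base.

    Seeds are found by grouping the oriented forms of all solid k-mers
    by their (k-1)-prefix; only groups of size >= 2 can host a bubble's
    left fork.  Within a pair, the k-mer with the smaller last base
    comes first, which halves the seed orbit.
    """
    arr = g.solid.members_array
    if arr.size == 0:
        return
    k = g.spec.k
    oriented = np.unique(
        np.concatenate([arr, revcomp_int_array(arr, k)])
    )
    prefix = oriented >> np.uint64(2)
    order = np.argsort(prefix, kind="stable")
    oriented = oriented[order]
    prefix = prefix[order]
    boundaries = np.nonzero(np.diff(prefix))[0] + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [prefix.size]])
    for s, e in zip(starts.tolist(), ends.tolist()):
        if e - s < 2:
            continue
        group = oriented[s:e].tolist()
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                yield int(group[i]), int(group[j])


def find_snp_bubbles(
    g: DeBruijnGraph, branching_mode: str = "strict"
) -> list[SnpBubble]:
    """Enumerate isolated-SNP bubbles; deduplicated, sorted, ids assigned."""
    if branching_mode not in ("strict", "relaxed"):
        raise ValueError("branching_mode must be 'strict' or 'relaxed'")
    k = g.spec.k
    mask = g._mask
    found: set[tuple[str, str]] = set()

    for x1, x2 in _seed_pairs(g):
        # simultaneous extension of both paths by k-1 shared bases
        if branching_mode == "strict":
            # strict extension keeps the two paths vertex-disjoint at the
            # canonical level: a candidate window whose canonical form is
            # already on either path (or equals its partner's) would make
            # the paths touch, which the bubble model excludes.  Without
            # this rule tiny strand-symmetric graphs branch spuriously.
            w1, w2 = x1, x2
            used = {canonical_int(x1, k), canonical_int(x2, k)}
            ext: list[str] = []
            ok = True
            for _ in range(k - 1):
                choices = []
                for b in range(4):
                    y1 = ((w1 << 2) & mask) | b
                    y2 = ((w2 << 2) & mask) | b
                    if not (g.has_oriented(y1) and g.has_oriented(y2)):
                        continue
                    c1, c2 = canonical_int(y1, k), canonical_int(y2, k)
                    if c1 == c2 or c1 in used or c2 in used:
                        continue
                    choices.append((b, y1, y2, c1, c2))
                if len(choices) != 1:
                    ok = False
                    break
                b, w1, w2, c1, c2 = choices[0]
                used.update((c1, c2))
                ext.append(_BASES[b])
            if ok:
                e = "".join(ext)
                found.add(
                    canonical_path_pair(decode_kmer(x1, k) + e, decode_kmer(x2, k) + e)
                )
        else:
            stack = [(x1, x2, "")]
            while stack:
                w1, w2, ext = stack.pop()
                if len(ext) == k - 1:
                    found.add(
                        canonical_path_pair(
                            decode_kmer(x1, k) + ext, decode_kmer(x2, k) + ext
                        )
                    )
                    continue
                for b in range(4):
                    y1 = ((w1 << 2) & mask) | b
                    y2 = ((w2 << 2) & mask) | b
                    if g.has_oriented(y1) and g.has_oriented(y2):
                        stack.append((y1, y2, ext + _BASES[b]))

    bubbles = [SnpBubble(pa, pb) for pa, pb in sorted(found)]
    for i, bub in enumerate(bubbles):
        bub.bubble_id = i
    return bubbles


def extend_flanks(g: DeBruijnGraph, bubble: SnpBubble, max_len: int = 10_000) -> SnpBubble:
    """Attach left/right unitig contigs shared by both alleles.

    The flank is entered through the unique neighbor shared by both
    first (resp. last) path windows — both alleles share it since the
    windows agree on k-1 positions — then follows the standard
    both-sides-unique unitig rule.  No unique neighbor means no contig.
    """
    k = bubble.k
    first = bubble.path_a[:k]
    preds = g.predecessors(first)
    left = ""
    if len(preds) == 1:
        p = preds[0]
        left = g.extend_unitig(p, "left", max_len) + p[0]
    last = bubble.path_a[-k:]
    succs = g.successors(last)
    right = ""
    if len(succs) == 1:
        s = succs[0]
        right = s[-1] + g.extend_unitig(s, "right", max_len)
    bubble.left_contig = left
    bubble.right_contig = right
    return bubble


# ---------------------------------------------------------------------------
# multi-FASTA emission: consecutive record pairs are the two alleles
# ---------------------------------------------------------------------------

def _bubble_header(bub: SnpBubble, which: str, set_names: list[str] | None) -> str:
    parts = [
        f"SNP_{bub.bubble_id}",
        f"P_{which}",
        f"left={len(bub.left_contig)}",
        f"right={len(bub.right_contig)}",
    ]
    if bub.counts is not None and set_names is not None:
        row = 0 if which == "A" else 1
        for s, name in enumerate(set_names):
            parts.append(f"C_{name}={int(bub.counts.table[row, s])}")
    if bub.phi is not None:
        parts.append(f"phi={bub.phi:.6f}")
    return "|".join(parts)


def write_bubbles_fasta(
    bubbles: list[SnpBubble],
    path: str,
    set_names: list[str] | None = None,
    header_lines: list[str] | None = None,
) -> int:
    """Write each bubble as two consecutive FASTA records (alleles A, B)."""
    records = []
    for bub in bubbles:
        for which in ("A", "B"):
            records.append(
                SequenceRecord(_bubble_header(bub, which, set_names), bub.flanked(which))
            )
    write_fasta(records, path, line_width=0, header_lines=header_lines or [])
    return len(records) // 2


_HEADER_RE = re.compile(r"^SNP_(\d+)\|P_([AB])\|left=(\d+)\|right=(\d+)")


def parse_bubbles_fasta(path: str) -> list[SnpBubble]:
    """Inverse of :func:`write_bubbles_fasta` (counts/phi re-attached lazily)."""
    from .quantify import AlleleCounts

    records = list(read_sequences(path))
    if len(records) % 2:
        raise ValueError(f"{path}: odd number of records in bubble FASTA")
    bubbles = []
    for i in range(0, len(records), 2):
        ra, rb = records[i], records[i + 1]
        ma = _HEADER_RE.match(ra.identifier)
        mb = _HEADER_RE.match(rb.identifier)
        if not ma or not mb or ma.group(1) != mb.group(1):
            raise ValueError(f"{path}: malformed bubble pair at record {i + 1}")
        left, right = int(ma.group(3)), int(ma.group(4))
        seq_a = ra.sequence[left : len(ra.sequence) - right]
        seq_b = rb.sequence[left : len(rb.sequence) - right]
        bub = SnpBubble(
            seq_a,
            seq_b,
            left_contig=ra.sequence[:left],
            right_contig=ra.sequence[len(ra.sequence) - right :],
            bubble_id=int(ma.group(1)),
        )
        fields = dict(
            f.split("=", 1) for f in ra.identifier.split("|")[2:] if "=" in f
        )
        fields_b = dict(
            f.split("=", 1) for f in rb.identifier.split("|")[2:] if "=" in f
        )
        names = [key[2:] for key in fields if key.startswith("C_")]
        if names:
            table = np.array(
                [
                    [int(fields[f"C_{n}"]) for n in names],
                    [int(fields_b[f"C_{n}"]) for n in names],
                ],
                dtype=np.int64,
            )
            bub.counts = AlleleCounts(table=table, set_names=names)
        if "phi" in fields:
            bub.phi = float(fields["phi"])
        bubbles.append(bub)
    return bubbles
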