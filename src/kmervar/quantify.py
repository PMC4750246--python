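"""Read map-back onto predicted alleles, per-set coverage, phi ranking.

Reads are mapped back, ungapped and anchored by at least one exact
shared k-mer, onto the flanked sequence of each allele of each bubble.
A placement supports an allele only if its overlap covers the variant
position (otherwise the read carries no allelic information).  A read
whose best placements tie between the two alleles is ambiguous and
counted for neither.

Bubbles are then ranked by the *phi score*: a normalized chi-squared
statistic in [0, 1] over the 2 x S allele-by-read-set contingency
table, sqrt(chi2 / N) (Cramér's V for a two-row table).  It is highest
for SNPs whose allele usage is most discriminant between the samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seq_io import SequenceRecord
from .snp_caller import SnpBubble

__all__ = [
    "AlleleCounts",
    "map_read",
    "quantify_bubbles",
    "phi_score",
    "rank_bubbles",
    "write_counts_tsv",
]


_RC_N = str.maketrans("ACGTN", "TGCAN")


def _rc_with_n(seq: str) -> str:
    return seq.translate(_RC_N)[::-1]


@dataclass
class AlleleCounts:
    """2 x S table of supporting-read counts: rows alleles A/B, columns sets."""

    table: np.ndarray
    set_names: list[str]

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.int64)
        if self.table.shape != (2, len(self.set_names)):
            raise ValueError("counts table must be 2 x len(set_names)")
        if (self.table < 0).any():
            raise ValueError("negative allele counts")


def _placement_mismatches(
    read: str, target: str, offset: int, k: int
) -> tuple[int, int, int] | None:
    """(mismatches, ov_start, ov_end) for read placed at ``offset`` on target.

    Returns None when the overlap is shorter than k or contains no
    length-k stretch of exact identity (the anchor requirement).
    """
    ov_start = max(0, offset)
    ov_end = min(len(target), offset + len(read))
    if ov_end - ov_start < k:
        return None
    mism = 0
    run = 0
    best_run = 0
    for t in range(ov_start, ov_end):
        if read[t - offset] == target[t]:
            run += 1
            best_run = max(best_run, run)
        else:
            mism += 1
            run = 0
    if best_run < k:
        return None
    return mism, ov_start, ov_end


def map_read(
    read: str,
    target: str,
    center: int,
    max_mismatch: int = 1,
    k: int = 31,
) -> bool:
    """Does the read support ``target`` at its variant position?

    True iff some ungapped placement of the read (either strand),
    anchored by >= 1 exact shared k-mer, has <= ``max_mismatch``
    mismatches over the overlap and the overlap covers ``center``.
    """
    best = best_map_mismatches(read, target, center, max_mismatch, k)
    return best is not None


def best_map_mismatches(
    read: str,
    target: str,
    center: int,
    max_mismatch: int,
    k: int,
) -> int | None:
    """Minimum mismatch count over admissible placements, or None."""
    best: int | None = None
    for oriented in (read, _rc_with_n(read)):
        for offset in range(-len(oriented) + 1, len(target)):
            res = _placement_mismatches(oriented, target, offset, k)
            if res is None:
                continue
            mism, ov_start, ov_end = res
            if mism > max_mismatch or not (ov_start <= center < ov_end):
                continue
            if best is None or mism < best:
                best = mism
    return best


def _index_targets(
    bubbles: Sequence[SnpBubble], k: int
) -> dict[str, list[tuple[int, int, int]]]:
    """Exact k-mer -> [(bubble index, allele row, target position)]."""
    index: dict[str, list[tuple[int, int, int]]] = {}
    for bi, bub in enumerate(bubbles):
        for row, which in enumerate("AB"):
            seq = bub.flanked(which)
            for pos in range(len(seq) - k + 1):
                index.setdefault(seq[pos : pos + k], []).append((bi, row, pos))
    return index


def quantify_bubbles(
    bubbles: Sequence[SnpBubble],
    readsets: Sequence[tuple[str, Iterable[SequenceRecord]]],
    max_mismatch: int = 1,
    k: int | None = None,
) -> list[SnpBubble]:
    """Attach per-allele per-set supporting-read counts to each bubble.

    ``readsets`` is an ordered list of (set name, record iterable).
    Counting follows :func:`map_read` semantics, made practical by an
    inverted exact-k-mer index over the flanked allele sequences: a
    read is only evaluated against placements sharing a k-mer with it,
    which is exactly the anchor requirement.
    """
    if not bubbles:
        return []
    if k is None:
        k = bubbles[0].k
    set_names = [name for name, _ in readsets]
    for bub in bubbles:
        bub.counts = AlleleCounts(
            np.zeros((2, len(set_names)), dtype=np.int64), list(set_names)
        )
    index = _index_targets(bubbles, k)
    targets = [(bub.flanked("A"), bub.flanked("B")) for bub in bubbles]
    centers = [bub.flanked_center for bub in bubbles]

    for s, (_, records) in enumerate(readsets):
        for rec in records:
            orientations = (rec.sequence, _rc_with_n(rec.sequence))
            # candidate placements from shared k-mers, both strands
            cands: dict[tuple[int, int, int], None] = {}
            for oi, oriented in enumerate(orientations):
                for rpos in range(len(oriented) - k + 1):
                    hits = index.get(oriented[rpos : rpos + k])
                    if hits:
                        for bi, row, tpos in hits:
                            cands[(bi * 2 + row, oi, tpos - rpos)] = None
            if not cands:
                continue
            best: dict[int, dict[int, int]] = {}
            for (slot, oi, offset), _n in cands.items():
                bi, row = divmod(slot, 2)
                oriented = orientations[oi]
                res = _placement_mismatches(oriented, targets[bi][row], offset, k)
                if res is None:
                    continue
                mism, ov_s, ov_e = res
                if mism > max_mismatch or not (ov_s <= centers[bi] < ov_e):
                    continue
                prev = best.setdefault(bi, {}).get(row)
                if prev is None or mism < prev:
                    best[bi][row] = mism
            for bi, rows in best.items():
                if len(rows) == 2 and rows[0] == rows[1]:
                    continue  # ambiguous: equal best match to both alleles
                row = min(rows, key=lambda r: rows[r])
                bubbles[bi].counts.table[row, s] += 1
    return list(bubbles)


def phi_score(counts: AlleleCounts | np.ndarray) -> float:
    """Normalized chi-squared statistic in [0, 1] over a 2 x S table.

    phi = sqrt(chi2 / N) with chi2 summed over cells whose expected
    value (rowsum * colsum / N) is positive; zero-marginal columns are
    skipped.  Degenerate tables (empty, one empty row, all-empty
    columns) score 0.  For S = 2 this equals the absolute classical phi
    coefficient |ad - bc| / sqrt((a+b)(c+d)(a+c)(b+d)).
    """
    table = counts.table if isinstance(counts, AlleleCounts) else np.asarray(counts)
    table = np.asarray(table, dtype=np.float64)
    if (table < 0).any():
        raise ValueError("negative entries in counts table")
    n = table.sum()
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if n == 0 or (row == 0).any() or (col == 0).all():
        return 0.0
    keep = col > 0
    expected = np.outer(row, col[keep]) / n
    chi2 = ((table[:, keep] - expected) ** 2 / expected).sum()
    return float(min(1.0, math.sqrt(chi2 / n)))


def rank_bubbles(bubbles: Sequence[SnpBubble]) -> list[SnpBubble]:
    """Sort by descending phi, ties broken by ascending bubble id."""
    for bub in bubbles:
        if bub.phi is None:
            bub.phi = phi_score(bub.counts) if bub.counts is not None else 0.0
    return sorted(bubbles, key=lambda b: (-b.phi, b.bubble_id))


def write_counts_tsv(
    bubbles: Sequence[SnpBubble], path: str, header_lines: Sequence[str] = ()
) -> None:
    """TSV: bubble_id, phi, then per-set C_A_<set> and C_B_<set> columns."""
    with open(path, "w") as out:
        for line in header_lines:
            out.write(f"#{line}\n")
        names = bubbles[0].counts.set_names if bubbles and bubbles[0].counts else []
        cols = ["bubble_id", "phi"]
        for n in names:
            cols += [f"C_A_{n}", f"C_B_{n}"]
        out.write("\t".join(cols) + "\n")
        for bub in bubbles:
            row = [str(bub.bubble_id), f"{bub.phi:.6f}" if bub.phi is not None else "NA"]
            if bub.counts is not None:
                for s in range(len(names)):
                    row += [
                        str(int(bub.counts.table[0, s])),
                        str(int(bub.counts.table[1, s])),
                    ]
            out.write("\t".join(row) + "\n")
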