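"""All-against-all read-set comparison through shared k-mers.

Each read set is indexed by its k-mers (exact set by default, bloom
filter optionally).  A read of a query set is *similar to* an indexed
set when at least ``t`` of its k-mer windows (canonical, overlapping
allowed) are present in the index; the per-read outcomes form a
compact bit vector that supports the usual logical set algebra.
Directed percentages of similar reads are folded into a symmetric
similarity matrix, which feeds average-linkage hierarchical clustering
rendered as a newick dendrogram.

Because a bloom filter has false positives but no false negatives,
bit vectors computed against a bloom index always contain those
computed against the exact index of the same set.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from skbio.tree import TreeNode

from .kmer_index import (
    BloomFilter,
    KmerSpec,
    SolidSet,
    build_bloom,
    build_solid_set,
    canonical_kmer_array,
    count_kmers,
)
from .seq_io import SequenceRecord

__all__ = [
    "SharedBitVector",
    "SimilarityMatrix",
    "build_readset_index",
    "mark_shared",
    "combine",
    "similarity_matrix",
    "cluster_dendrogram",
]


@dataclass
class SharedBitVector:
    """One bit per read of a query set: similar to the indexed set or not."""

    set_name: str
    against_name: str
    bits: np.ndarray  # bool, one per read in input order
    k: int
    t: int

    @property
    def n_reads(self) -> int:
        return int(self.bits.size)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    MAGIC = b"KVBV1\x00"

    def save(self, path: str) -> None:
        """Versioned binary format: magic, k, t, names, n_reads, packed bits."""
        name_a = self.set_name.encode()
        name_b = self.against_name.encode()
        with open(path, "wb") as out:
            out.write(self.MAGIC)
            out.write(struct.pack("<iiHHq", self.k, self.t, len(name_a), len(name_b), self.n_reads))
            out.write(name_a)
            out.write(name_b)
            out.write(np.packbits(self.bits).tobytes())

    @classmethod
    def load(cls, path: str) -> "SharedBitVector":
        with open(path, "rb") as fh:
            if fh.read(len(cls.MAGIC)) != cls.MAGIC:
                raise ValueError(f"{path}: not a shared-bit-vector file")
            k, t, la, lb, n = struct.unpack("<iiHHq", fh.read(20))
            name_a = fh.read(la).decode()
            name_b = fh.read(lb).decode()
            packed = np.frombuffer(fh.read(), dtype=np.uint8)
        bits = np.unpackbits(packed)[:n].astype(bool)
        return cls(name_a, name_b, bits, k, t)


def build_readset_index(
    records: list[SequenceRecord],
    k: int,
    use_bloom: bool = False,
    bits_per_elem: int = 16,
    h: int = 7,
    seed: int = 0,
) -> SolidSet | BloomFilter:
    """Index every k-mer of a read set (solidity threshold 1)."""
    table = count_kmers([records], KmerSpec(k))
    solid = build_solid_set(table, 1)
    if use_bloom:
        return build_bloom(solid, bits_per_elem=bits_per_elem, h=h, seed=seed)
    return solid


def mark_shared(
    query: list[SequenceRecord],
    index: SolidSet | BloomFilter,
    t: int = 2,
    set_name: str = "query",
    against_name: str = "target",
) -> SharedBitVector:
    """Bit i is 1 iff read i shares >= t canonical k-mers with the index.

    Reads shorter than k get bit 0.  Overlapping shared windows count
    individually.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    k = index.k
    if k is None:
        raise ValueError("index does not record its k")
    bits = np.zeros(len(query), dtype=bool)
    for i, rec in enumerate(query):
        kmers = canonical_kmer_array(rec.sequence, k)
        if kmers.size == 0:
            continue
        if isinstance(index, SolidSet):
            hits = int(index.contains_canonical_array(kmers).sum())
        else:
            hits = int(index.query_array(kmers).sum())
        bits[i] = hits >= t
    return SharedBitVector(set_name, against_name, bits, k, t)


def combine(
    x: SharedBitVector, y: SharedBitVector | None, op: str
) -> SharedBitVector:
    """Bitwise AND/OR/ANDNOT of two vectors, or unary NOT of the first.

    Operands must describe the same query set (same name and length);
    the resulting metadata records the expression.
    """
    op = op.upper()
    if op == "NOT":
        return SharedBitVector(
            x.set_name, f"NOT({x.against_name})", ~x.bits, x.k, x.t
        )
    if y is None:
        raise ValueError(f"binary operation {op} needs two vectors")
    if x.set_name != y.set_name or x.n_reads != y.n_reads:
        raise ValueError("operands describe different read sets")
    if op == "AND":
        bits = x.bits & y.bits
    elif op == "OR":
        bits = x.bits | y.bits
    elif op == "ANDNOT":
        bits = x.bits & ~y.bits
    else:
        raise ValueError(f"unknown operation {op!r}")
    return SharedBitVector(
        x.set_name, f"({x.against_name} {op} {y.against_name})", bits, x.k, x.t
    )


@dataclass
class SimilarityMatrix:
    """Directed shared-read percentages and their symmetric fold."""

    set_names: list[str]
    directed: np.ndarray  # directed[i, j] = pct(set_i -> set_j)
    symmetric: np.ndarray

    def to_tsv(self, which: str = "symmetric") -> str:
        mat = self.symmetric if which == "symmetric" else self.directed
        lines = ["\t".join(["set"] + self.set_names)]
        for i, name in enumerate(self.set_names):
            lines.append(
                "\t".join([name] + [f"{mat[i, j]:.4f}" for j in range(len(self.set_names))])
            )
        return "\n".join(lines) + "\n"


def similarity_matrix(
    sets: list[tuple[str, list[SequenceRecord]]],
    k: int,
    t: int = 2,
    use_bloom: bool = False,
) -> SimilarityMatrix:
    """All-against-all comparison of read sets.

    pct(A->B) = 100 * |reads of A similar to B| / |A|;
    sym(A, B) = 100 * (shared(A->B) + shared(B->A)) / (|A| + |B|),
    with sym(A, A) = 100 by definition.
    """
    if len(sets) < 2:
        raise ValueError("need at least two read sets")
    for name, records in sets:
        if not records:
            raise ValueError(f"read set {name!r} is empty")
    names = [name for name, _ in sets]
    indexes = [
        build_readset_index(records, k, use_bloom=use_bloom, seed=i)
        for i, (_, records) in enumerate(sets)
    ]
    s = len(sets)
    shared = np.zeros((s, s), dtype=np.int64)
    sizes = np.array([len(records) for _, records in sets], dtype=np.int64)
    for i, (name_i, records_i) in enumerate(sets):
        for j in range(s):
            if i == j:
                continue
            bv = mark_shared(records_i, indexes[j], t, name_i, names[j])
            shared[i, j] = bv.popcount
    directed = 100.0 * shared / sizes[:, None]
    np.fill_diagonal(directed, 100.0)
    symmetric = np.zeros((s, s), dtype=float)
    for i in range(s):
        for j in range(s):
            if i == j:
                symmetric[i, j] = 100.0
            else:
                symmetric[i, j] = (
                    100.0 * (shared[i, j] + shared[j, i]) / (sizes[i] + sizes[j])
                )
    return SimilarityMatrix(names, directed, symmetric)


def cluster_dendrogram(m: SimilarityMatrix) -> tuple[str, list[str]]:
    """Average-linkage dendrogram on distance 100 - similarity.

    Returns (newick text with branch lengths, leaf order).  Input rows
    are taken in set-name order so equal-distance merges resolve
    deterministically.
    """
    s = len(m.set_names)
    if s < 2:
        raise ValueError("need at least two sets to cluster")
    order = np.argsort(m.set_names, kind="stable")
    names = [m.set_names[i] for i in order]
    dist = 100.0 - m.symmetric[np.ix_(order, order)]
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, dist.T)  # guard rounding asymmetry
    linkage = sch.linkage(squareform(dist, checks=False), method="average")
    tree = TreeNode.from_linkage_matrix(linkage, names)
    buf = io.StringIO()
    tree.write(buf, format="newick")
    leaf_order = [names[i] for i in sch.leaves_list(linkage)]
    return buf.getvalue().strip(), leaf_order
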