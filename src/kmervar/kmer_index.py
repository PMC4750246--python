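"""k-mer extraction, canonicalization, counting, solidity, bloom filter.

This is the shared kernel of every method in the package.  k-mers are
packed 2 bits per base (A=0, C=1, G=2, T=3) into a machine word, which
caps k at 31.  All membership structures are *strand-neutral*: the
representative of a k-mer is its canonical form, the lexicographic
minimum of the k-mer and its reverse complement.

Two membership structures are provided.  The exact :class:`SolidSet`
(k-mers occurring at least ``c`` times) is the membership truth for all
downstream graph algorithms.  The probabilistic :class:`BloomFilter` is
a low-memory prefilter: it never produces false negatives, and its
false-positive rate on never-inserted items follows the classical
``(1 - e^(-h*n/m))^h`` closed form.  When a graph carries both, queries
hit the bloom filter first and are confirmed in the exact set.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "KmerSpec",
    "CountTable",
    "SolidSet",
    "BloomFilter",
    "reverse_complement",
    "canonical",
    "iter_kmers",
    "count_kmers",
    "build_solid_set",
    "build_bloom",
    "encode_kmer",
    "decode_kmer",
    "revcomp_int",
    "revcomp_int_array",
    "canonical_int",
    "canonical_kmer_array",
    "oriented_kmer_array",
]

COUNT_SATURATION = 2**16 - 1

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

# byte -> base code; 4 marks anything that is not A/C/G/T
_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _c in _CODE.items():
    _CODE_LUT[ord(_b)] = _c

# reverse-complement of a packed byte (4 bases), used 8 bits at a time
_RC_BYTE = np.empty(256, dtype=np.uint64)
for _x in range(256):
    _y = 0
    _v = _x
    for _ in range(4):
        _y = (_y << 2) | (3 - (_v & 3))
        _v >>= 2
    _RC_BYTE[_x] = _y


# ---------------------------------------------------------------------------
# string-level primitives
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A<->T, C<->G, order reversed)."""
    if any(ch not in "ACGT" for ch in seq):
        raise ValueError(f"non-ACGT character in sequence {seq[:50]!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass(frozen=True)
class KmerSpec:
    """k-mer length and strand handling (canonical mode is always on).

    k must lie in [3, 31] so a k-mer packs into one 64-bit word.  Odd k
    is recommended: even k admits self-reverse-complement k-mers, which
    blur strand-neutral counting.
    """

    k: int = 31
    canonical_mode: bool = True

    def __post_init__(self) -> None:
        if not (3 <= self.k <= 31):
            raise ValueError(f"k must be in [3, 31], got {self.k}")
        if self.k % 2 == 0:
            warnings.warn(
                f"even k={self.k}: self-reverse-complement k-mers possible",
                stacklevel=3,
            )


def iter_kmers(seq: str, spec: KmerSpec) -> Iterator[tuple[int, str]]:
    """Yield ``(position, oriented k-mer)`` for every valid window.

    Windows containing any non-ACGT character are skipped wholesale.
    """
    k = spec.k
    n = len(seq)
    if n < k:
        return
    # rightmost invalid position at or after i decides window validity
    next_bad = -1
    bad = [i for i, ch in enumerate(seq) if ch not in "ACGT"]
    bad_iter = iter(bad + [n + k])
    next_bad = next(bad_iter)
    for i in range(n - k + 1):
        while next_bad < i:
            next_bad = next(bad_iter)
        if next_bad >= i + k:
            yield i, seq[i : i + k]


# ---------------------------------------------------------------------------
# integer packing
# ---------------------------------------------------------------------------

def encode_kmer(kmer: str) -> int:
    """Pack an ACGT string into an integer, 2 bits per base."""
    x = 0
    for ch in kmer:
        try:
            x = (x << 2) | _CODE[ch]
        except KeyError:
            raise ValueError(f"non-ACGT character {ch!r} in k-mer") from None
    return x


def decode_kmer(x: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    return "".join(_BASES[(x >> (2 * (k - 1 - i))) & 3] for i in range(k))


def revcomp_int(x: int, k: int) -> int:
    """Reverse complement of a packed k-mer, byte-table driven."""
    y = 0
    nbytes = (2 * k + 7) // 8
    for _ in range(nbytes):
        y = (y << 8) | int(_RC_BYTE[x & 0xFF])
        x >>= 8
    # the table works on whole bytes; shift out the padding
    return y >> (8 * nbytes - 2 * k)


def canonical_int(x: int, k: int) -> int:
    rc = revcomp_int(x, k)
    return x if x <= rc else rc


def revcomp_int_array(arr: np.ndarray, k: int) -> np.ndarray:
    """Vectorized :func:`revcomp_int` over a uint64 array."""
    x = arr.astype(np.uint64)
    y = np.zeros_like(x)
    for _ in range(8):
        y = (y << np.uint64(8)) | _RC_BYTE[(x & np.uint64(0xFF)).astype(np.int64)]
        x = x >> np.uint64(8)
    return y >> np.uint64(64 - 2 * k)


def _codes(seq: str) -> np.ndarray:
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _pack_windows(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every length-k window of a code array into uint64 (vectorized)."""
    win = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.uint64)
    shifts = (2 * np.arange(k - 1, -1, -1, dtype=np.uint64))
    return (win << shifts).sum(axis=1, dtype=np.uint64)


def kmer_window_arrays(
    seq: str, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized window packing: (positions, forward, reverse-complement).

    Only windows free of non-ACGT characters are returned; positions are
    0-based window starts.
    """
    codes = _codes(seq)
    n = codes.size
    if n < k:
        e = np.empty(0, dtype=np.uint64)
        return np.empty(0, dtype=np.int64), e, e
    fwd = _pack_windows(np.where(codes == 4, 0, codes), k)
    rc_codes = (3 - np.where(codes == 4, 0, codes).astype(np.int16)).astype(np.uint8)
    rev = _pack_windows(rc_codes[::-1], k)[::-1]
    valid = (
        np.lib.stride_tricks.sliding_window_view(codes == 4, k).any(axis=1) == False  # noqa: E712
    )
    pos = np.nonzero(valid)[0]
    return pos, fwd[valid], rev[valid]


def canonical_kmer_array(seq: str, k: int) -> np.ndarray:
    """Canonical packed k-mers of every valid window of ``seq``."""
    _, fwd, rev = kmer_window_arrays(seq, k)
    return np.minimum(fwd, rev)


def oriented_kmer_array(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(positions, forward-oriented packed k-mers) of valid windows."""
    pos, fwd, _ = kmer_window_arrays(seq, k)
    return pos, fwd


# ---------------------------------------------------------------------------
# counting and solidity
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Occurrence counts of canonical k-mers (saturating at 2^16 - 1).

    Keys are stored packed, sorted ascending, with aligned counts —
    lookups are binary searches, merges are array merges.
    """

    spec: KmerSpec
    keys: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.uint64)
    )
    counts: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )

    def __len__(self) -> int:
        return int(self.keys.size)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def get(self, kmer: str | int) -> int:
        """Count of one canonical k-mer (a string is canonicalized first)."""
        if isinstance(kmer, str):
            kmer = canonical_int(encode_kmer(kmer), self.spec.k)
        key = np.uint64(kmer)
        i = int(np.searchsorted(self.keys, key))
        if i < self.keys.size and self.keys[i] == key:
            return int(self.counts[i])
        return 0

    def get_many(self, kmers: np.ndarray) -> np.ndarray:
        """Vectorized count lookup for an array of canonical packed k-mers."""
        if self.keys.size == 0:
            return np.zeros(kmers.size, dtype=np.int64)
        idx = np.searchsorted(self.keys, kmers)
        idx = np.minimum(idx, self.keys.size - 1)
        hit = self.keys[idx] == kmers
        out = np.where(hit, self.counts[idx], 0)
        return out.astype(np.int64)

    def items(self) -> Iterator[tuple[str, int]]:
        k = self.spec.k
        for key, cnt in zip(self.keys.tolist(), self.counts.tolist()):
            yield decode_kmer(key, k), int(cnt)


def count_kmers(
    readsets: Iterable[Iterable["object"]], spec: KmerSpec
) -> CountTable:
    """Count canonical k-mers across all reads of all read sets pooled.

    ``readsets`` is a list of record iterables (``SequenceRecord`` or
    anything with a ``sequence`` attribute, or plain strings).
    """
    k = spec.k
    chunks: list[np.ndarray] = []
    buf: list[np.ndarray] = []
    buf_n = 0
    for records in readsets:
        for rec in records:
            seq = rec if isinstance(rec, str) else rec.sequence
            arr = canonical_kmer_array(seq, k)
            if arr.size:
                buf.append(arr)
                buf_n += arr.size
            if buf_n >= 4_000_000:
                concat = np.concatenate(buf)
                u, c = np.unique(concat, return_counts=True)
                chunks.append(np.stack([u, c.astype(np.uint64)]))
                buf, buf_n = [], 0
    if buf:
        concat = np.concatenate(buf)
        u, c = np.unique(concat, return_counts=True)
        chunks.append(np.stack([u, c.astype(np.uint64)]))
    if not chunks:
        return CountTable(spec)
    allk = np.concatenate([ch[0] for ch in chunks])
    allc = np.concatenate([ch[1] for ch in chunks]).astype(np.int64)
    order = np.argsort(allk, kind="stable")
    allk, allc = allk[order], allc[order]
    uniq, start = np.unique(allk, return_index=True)
    sums = np.add.reduceat(allc, start)
    sums = np.minimum(sums, COUNT_SATURATION)
    return CountTable(spec, uniq, sums)


@dataclass
class SolidSet:
    """Exact set of canonical k-mers with count >= c.

    Membership is exact — no false positives or negatives.  Alongside
    the canonical members, an *oriented* set holding both orientations
    of every member is kept so the graph layer can test a candidate
    k-mer without computing its reverse complement.
    """

    k: int
    c: int
    members_array: np.ndarray  # sorted canonical packed k-mers

    def __post_init__(self) -> None:
        arr = self.members_array
        rc = revcomp_int_array(arr, self.k)
        self._oriented: set[int] = set(arr.tolist()) | set(rc.tolist())
        self._canon: set[int] = set(arr.tolist())

    def __len__(self) -> int:
        return int(self.members_array.size)

    def __contains__(self, kmer: str | int) -> bool:
        if isinstance(kmer, str):
            return encode_kmer(kmer) in self._oriented
        return canonical_int(kmer, self.k) in self._canon

    def contains_oriented_int(self, x: int) -> bool:
        """Membership of an oriented packed k-mer (canonicalization-free)."""
        return x in self._oriented

    def contains_canonical_array(self, kmers: np.ndarray) -> np.ndarray:
        """Vectorized membership for an array of canonical packed k-mers."""
        if self.members_array.size == 0:
            return np.zeros(kmers.size, dtype=bool)
        idx = np.searchsorted(self.members_array, kmers)
        idx = np.minimum(idx, self.members_array.size - 1)
        return self.members_array[idx] == kmers

    def iter_members(self) -> Iterator[str]:
        for x in self.members_array.tolist():
            yield decode_kmer(x, self.k)

    # -- persistence (binary: magic, k, c, count, sorted packed k-mers) ----

    MAGIC = b"KVSS1\x00"

    def save(self, path: str) -> None:
        with open(path, "wb") as out:
            out.write(self.MAGIC)
            out.write(struct.pack("<iiq", self.k, self.c, len(self)))
            out.write(self.members_array.astype("<u8").tobytes())

    @classmethod
    def load(cls, path: str) -> "SolidSet":
        with open(path, "rb") as fh:
            magic = fh.read(len(cls.MAGIC))
            if magic != cls.MAGIC:
                raise ValueError(f"{path}: not a solid-set file")
            k, c, n = struct.unpack("<iiq", fh.read(16))
            arr = np.frombuffer(fh.read(8 * n), dtype="<u8").astype(np.uint64)
        return cls(k, c, arr)


def build_solid_set(table: CountTable, c: int) -> SolidSet:
    """Keep canonical k-mers whose count is at least the solidity threshold."""
    if c < 1:
        raise ValueError(f"solidity threshold c must be >= 1, got {c}")
    mask = table.counts >= c
    return SolidSet(table.spec.k, c, table.keys[mask].copy())


# ---------------------------------------------------------------------------
# bloom filter
# ---------------------------------------------------------------------------

def _splitmix64(x: np.ndarray | np.uint64) -> np.ndarray | np.uint64:
    """64-bit finalizer; statistically independent outputs per seed offset."""
    with np.errstate(over="ignore"):
        x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        return x ^ (x >> np.uint64(31))


class BloomFilter:
    """Bit-vector set membership: no false negatives, tunable false positives.

    Each item is hashed to ``h`` addresses (typically seven) via double
    hashing ``g_i = h1 + i*h2 mod m`` from two independent 64-bit hashes.
    Adding an item sets its bits to 1; an item is reported present iff
    all its bits are 1 — so a query can err only by answering yes.
    """

    def __init__(self, m_bits: int, h: int = 7, seed: int = 0, k: int | None = None):
        if m_bits < 1:
            raise ValueError("m_bits must be >= 1")
        if not (1 <= h <= 16):
            raise ValueError("h must be in [1, 16]")
        self.m = int(m_bits)
        self.h = int(h)
        self.seed = int(seed)
        self.k = k
        self.n_inserted = 0
        self.bits = np.zeros((self.m + 7) // 8, dtype=np.uint8)
        self._s1 = np.uint64(_splitmix64(np.uint64(seed * 2 + 1)))
        self._s2 = np.uint64(_splitmix64(np.uint64(seed * 2 + 2)))

    def _addresses(self, items: np.ndarray) -> np.ndarray:
        """(len(items), h) matrix of bit addresses."""
        items = items.astype(np.uint64)
        h1 = _splitmix64(items ^ self._s1)
        h2 = _splitmix64(items ^ self._s2) | np.uint64(1)
        i = np.arange(self.h, dtype=np.uint64)
        with np.errstate(over="ignore"):
            g = h1[:, None] + i[None, :] * h2[:, None]
        return (g % np.uint64(self.m)).astype(np.int64)

    def insert_array(self, items: np.ndarray) -> None:
        if items.size == 0:
            return
        addr = self._addresses(items).ravel()
        np.bitwise_or.at(self.bits, addr >> 3, (1 << (addr & 7)).astype(np.uint8))
        self.n_inserted += int(items.size)

    def query_array(self, items: np.ndarray) -> np.ndarray:
        if items.size == 0:
            return np.zeros(0, dtype=bool)
        addr = self._addresses(items)
        bit = (self.bits[addr >> 3] >> (addr & 7)) & 1
        return bit.all(axis=1)

    def insert(self, kmer: str | int) -> None:
        x = encode_kmer(kmer) if isinstance(kmer, str) else kmer
        self.insert_array(np.array([x], dtype=np.uint64))

    def query(self, kmer: str | int) -> bool:
        x = encode_kmer(kmer) if isinstance(kmer, str) else kmer
        return bool(self.query_array(np.array([x], dtype=np.uint64))[0])

    def expected_fp_rate(self) -> float:
        """Closed-form false-positive rate (1 - e^(-h n / m))^h."""
        if self.n_inserted == 0:
            return 0.0
        return float(
            (1.0 - np.exp(-self.h * self.n_inserted / self.m)) ** self.h
        )


def build_bloom(solid: SolidSet, bits_per_elem: int = 16, h: int = 7, seed: int = 0) -> BloomFilter:
    """Bloom filter over the canonical members of a solid set."""
    if bits_per_elem < 1:
        raise ValueError("bits_per_elem must be >= 1")
    m = bits_per_elem * max(1, len(solid))
    bf = BloomFilter(m, h=h, seed=seed, k=solid.k)
    bf.insert_array(solid.members_array)
    return bf
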