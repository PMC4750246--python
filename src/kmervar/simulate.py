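"""Synthetic genomes with planted variants, read simulation, evaluation.

The generator builds the study conditions under which the callers are
exercised: a random genome, an alternate haplotype carrying planted
isolated SNPs or inversions, and substitution-error shotgun reads from
each haplotype.  Planted variant windows are resampled until their
k-mers are unique in both haplotypes, which makes perfect recall under
error-free saturating coverage a structural guarantee rather than a
statistical hope; real data offer no such guarantee, so evaluation
numbers here measure the callers, not the biology.

Read errors are substitution-only: every implemented caller models
substitution-induced graph motifs, and indel-bearing reads would probe
machinery (splicing bubbles, long-read correction) outside this
package.  All generators are deterministic for a fixed seed, with
independent streams per purpose.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .inversion_caller import InversionEvent, canonicalize_event
from .kmer_index import canonical_kmer_array, reverse_complement
from .seq_io import SequenceRecord
from .snp_caller import SnpBubble, canonical_path_pair

__all__ = [
    "TruthRecord",
    "ReadSimConfig",
    "random_genome",
    "plant_snps",
    "plant_inversions",
    "simulate_reads",
    "evaluate_snps",
    "evaluate_inversions",
    "write_truth_tsv",
    "read_truth_tsv",
]

_BASES = "ACGT"


def _rng(seed: int, purpose: str) -> np.random.Generator:
    """Independent deterministic stream per (seed, purpose) label."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(purpose.encode())])
    )


@dataclass
class TruthRecord:
    """Ground truth for one planted variant.

    For SNPs: ``position`` is the 0-based substituted offset, ``detail``
    maps ref/alt bases and the ref/alt (2k-1)-windows centered there.
    For inversions: ``detail`` carries the half-open segment bounds and
    the four expected 2k breakpoint words.
    """

    kind: str  # "snp" | "inversion"
    position: int
    detail: dict


@dataclass
class ReadSimConfig:
    coverage: float = 30.0
    read_len: int = 100
    err_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.err_rate < 1.0):
            raise ValueError("err_rate must be in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


def random_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """i.i.d. random genome with the requested GC fraction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must be in (0, 1)")
    rng = _rng(seed, "genome")
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=p)
    return "".join(_BASES[c] for c in codes.tolist())


def _kmer_census(genomes: Sequence[str], k: int) -> dict[int, int]:
    """Canonical k-mer -> count across the given genomes."""
    arrays = [canonical_kmer_array(g, k) for g in genomes if len(g) >= k]
    if not arrays:
        return {}
    u, c = np.unique(np.concatenate(arrays), return_counts=True)
    return dict(zip(u.tolist(), c.tolist()))


def plant_snps(
    genome: str, n: int, k: int, seed: int = 0, max_retries_per_site: int = 200
) -> tuple[str, list[TruthRecord]]:
    """Plant n isolated substitutions; return (alt genome, truth records).

    Sites are sampled with pairwise separation >= 2k and >= 2k from the
    genome ends.  A site is accepted only when every k-mer of both its
    ref and alt (2k-1)-windows is unique within the two haplotypes, so
    each planted bubble is structurally recoverable; sites are
    resampled (boundedly) otherwise.
    """
    L = len(genome)
    if n == 0:
        return genome, []
    if L < 4 * k * (n + 1):
        raise ValueError(
            f"genome of length {L} cannot host {n} SNPs "
            f"with separation 2k={2 * k}"
        )
    rng = _rng(seed, "plant_snps")
    census = _kmer_census([genome], k)
    taken: list[int] = []
    planted_kmers: set[int] = set()
    truth: list[TruthRecord] = []
    alt = list(genome)
    retries = max_retries_per_site * n
    while len(truth) < n:
        if retries <= 0:
            raise RuntimeError(
                f"could not place {n} unique isolated SNPs "
                f"(placed {len(truth)}); genome too small or repetitive"
            )
        retries -= 1
        pos = int(rng.integers(2 * k, L - 2 * k))
        if any(abs(pos - q) < 2 * k for q in taken):
            continue
        ref_base = genome[pos]
        alt_base = _BASES[(_BASES.index(ref_base) + int(rng.integers(1, 4))) % 4]
        ref_window = genome[pos - (k - 1) : pos + k]
        alt_window = ref_window[: k - 1] + alt_base + ref_window[k:]
        ref_kmers = canonical_kmer_array(ref_window, k)
        alt_kmers = canonical_kmer_array(alt_window, k)
        # ref windows unique in the reference; alt windows absent from it
        if any(census.get(int(x), 0) != 1 for x in ref_kmers):
            continue
        if any(census.get(int(x), 0) != 0 for x in alt_kmers):
            continue
        new = set(alt_kmers.tolist())
        if new & planted_kmers or len(new) < k:
            continue
        planted_kmers |= new
        taken.append(pos)
        alt[pos] = alt_base
        truth.append(
            TruthRecord(
                "snp",
                pos,
                {
                    "ref": ref_base,
                    "alt": alt_base,
                    "ref_window": ref_window,
                    "alt_window": alt_window,
                },
            )
        )
    truth.sort(key=lambda t: t.position)
    return "".join(alt), truth


def plant_inversions(
    genome: str,
    n: int,
    min_len: int,
    max_len: int,
    k: int,
    seed: int = 0,
    min_fork_distance: int = 3,
    max_retries_per_site: int = 500,
) -> tuple[str, list[TruthRecord]]:
    """Reverse-complement n non-overlapping segments; return alt + truth.

    Segment lengths are drawn from [min_len, max_len] (min_len >= 2k).
    A placement is accepted only when the flank k-mers a, b and segment
    terminals u, v are unique in the genome, non-palindromic, locally
    dissimilar (Hamming(u, v') >= ``min_fork_distance``) and fork-visible
    (the first bases towards u and v' differ), which makes the planted
    motif detectable by the breakpoint search under its default guards.
    """
    L = len(genome)
    if min_len < 2 * k:
        raise ValueError(f"min_len must be >= 2k={2 * k}")
    if n == 0:
        return genome, []
    rng = _rng(seed, "plant_inversions")
    census = _kmer_census([genome], k)
    segments: list[tuple[int, int]] = []
    truth: list[TruthRecord] = []
    retries = max_retries_per_site * n
    while len(truth) < n:
        if retries <= 0:
            raise RuntimeError(
                f"could not place {n} inversions (placed {len(truth)})"
            )
        retries -= 1
        seg_len = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(2 * k, L - seg_len - 2 * k))
        end = start + seg_len
        if any(s - 2 * k < end and start < e + 2 * k for s, e in segments):
            continue
        a = genome[start - k : start]
        b = genome[end : end + k]
        u = genome[start : start + k]
        v = genome[end - k : end]
        vp = reverse_complement(v)
        four = [a, u, v, b]
        if any(x == reverse_complement(x) for x in four):
            continue
        if sum(ch1 != ch2 for ch1, ch2 in zip(u, vp)) < max(1, min_fork_distance):
            continue
        if u[0] == vp[0]:  # fork invisible: a would have one successor
            continue
        # breakpoint micro-homology makes the segment coordinates (and
        # hence the breakpoint motif) ambiguous: growing the segment by
        # one base on both sides describes the same rearrangement when
        # the flanking bases pair
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        if genome[start - 1] == comp[genome[end]]:
            continue
        distinct = {int(canonical_kmer_array(x, k)[0]) for x in four}
        if len(distinct) < 4 or any(census.get(key, 0) != 1 for key in distinct):
            continue
        segments.append((start, end))
        truth.append(
            TruthRecord(
                "inversion",
                start,
                {
                    "start": start,
                    "end": end,
                    "au": a + u,
                    "vb": v + b,
                    "avp": a + vp,
                    "upb": reverse_complement(u) + b,
                },
            )
        )
    alt = list(genome)
    for start, end in segments:
        alt[start:end] = reverse_complement(genome[start:end])
    truth.sort(key=lambda t: t.position)
    return "".join(alt), truth


def simulate_reads(
    genome: str, cfg: ReadSimConfig, set_name: str = "sample"
) -> Iterator[SequenceRecord]:
    """Shotgun substitution-error reads at the configured coverage.

    ceil(coverage * L / read_len) reads with uniform start positions,
    a fair strand coin, and i.i.d. substitutions at ``err_rate`` to a
    uniformly chosen different base.  Qualities are constant (and never
    interpreted downstream).
    """
    L = len(genome)
    rl = cfg.read_len
    if rl > L:
        raise ValueError(f"read_len {rl} exceeds genome length {L}")
    rng = _rng(cfg.seed, f"reads:{set_name}")
    n_reads = math.ceil(cfg.coverage * L / rl)
    code_lut = {ch: i for i, ch in enumerate(_BASES)}
    gcodes = np.fromiter((code_lut.get(ch, 0) for ch in genome), dtype=np.int8, count=L)
    starts = rng.integers(0, L - rl + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    base_lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in range(n_reads):
        codes = gcodes[starts[i] : starts[i] + rl].copy()
        if strands[i]:
            codes = (3 - codes)[::-1]
        if cfg.err_rate > 0:
            mask = rng.random(rl) < cfg.err_rate
            n_err = int(mask.sum())
            if n_err:
                codes[mask] = (codes[mask] + rng.integers(1, 4, size=n_err)) % 4
        seq = base_lut[codes].tobytes().decode("ascii")
        yield SequenceRecord(f"{set_name}_{i}", seq, "I" * rl)


# ---------------------------------------------------------------------------
# truth-based evaluation
# ---------------------------------------------------------------------------

def evaluate_snps(
    predicted: Sequence[SnpBubble], truth: Sequence[TruthRecord], k: int
) -> tuple[float, float, list[int]]:
    """(recall, precision, matched truth indices) for SNP predictions.

    A truth record is recovered when some predicted bubble's path pair
    equals (up to reverse-complement canonicalization) its ref/alt
    windows.  Predictions are deduplicated before matching; each
    prediction matches at most one truth record.  Empty predictions
    give precision 1 (vacuous); empty truth gives recall 1.
    """
    truth_keys = {}
    for i, rec in enumerate(truth):
        if rec.kind != "snp":
            continue
        key = canonical_path_pair(rec.detail["ref_window"], rec.detail["alt_window"])
        truth_keys[key] = i
    pred_keys = {canonical_path_pair(b.path_a, b.path_b) for b in predicted}
    matched = sorted(truth_keys[key] for key in pred_keys if key in truth_keys)
    n_truth = len(truth_keys)
    recall = len(matched) / n_truth if n_truth else 1.0
    precision = (
        sum(1 for key in pred_keys if key in truth_keys) / len(pred_keys)
        if pred_keys
        else 1.0
    )
    return recall, precision, matched


def evaluate_inversions(
    predicted: Sequence[InversionEvent], truth: Sequence[TruthRecord]
) -> tuple[float, float]:
    """(recall, precision) matching canonical breakpoint motifs exactly."""
    truth_keys = set()
    for rec in truth:
        if rec.kind != "inversion":
            continue
        d = rec.detail
        k = len(d["au"]) // 2
        ev = canonicalize_event(d["au"][:k], d["au"][k:], d["vb"][:k], d["vb"][k:])
        truth_keys.add(ev.serialized())
    pred_keys = {
        canonicalize_event(e.a, e.u, e.v, e.b).serialized() for e in predicted
    }
    recall = (
        len(pred_keys & truth_keys) / len(truth_keys) if truth_keys else 1.0
    )
    precision = (
        len(pred_keys & truth_keys) / len(pred_keys) if pred_keys else 1.0
    )
    return recall, precision


# ---------------------------------------------------------------------------
# truth persistence (TSV)
# ---------------------------------------------------------------------------

def write_truth_tsv(truth: Sequence[TruthRecord], path: str) -> None:
    import json

    with open(path, "w") as out:
        out.write("#kind\tposition\tdetail_json\n")
        for rec in truth:
            out.write(f"{rec.kind}\t{rec.position}\t{json.dumps(rec.detail, sort_keys=True)}\n")


def read_truth_tsv(path: str) -> list[TruthRecord]:
    import json

    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            kind, pos, detail = line.rstrip("\n").split("\t")
            out.append(TruthRecord(kind, int(pos), json.loads(detail)))
    return out
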