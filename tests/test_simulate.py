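import math

import numpy as np
import pytest

from kmervar.inversion_caller import InversionEvent, canonicalize_event
from kmervar.kmer_index import canonical, reverse_complement
from kmervar.simulate import (
    ReadSimConfig,
    TruthRecord,
    evaluate_inversions,
    evaluate_snps,
    plant_inversions,
    plant_snps,
    random_genome,
    read_truth_tsv,
    simulate_reads,
    write_truth_tsv,
)
from kmervar.snp_caller import SnpBubble


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def test_random_genome_validation_and_determinism():
    with pytest.raises(ValueError):
        random_genome(0)
    with pytest.raises(ValueError):
        random_genome(10, gc=1.0)
    assert len(random_genome(1, seed=3)) == 1
    assert random_genome(500, seed=9) == random_genome(500, seed=9)
    assert random_genome(500, seed=9) != random_genome(500, seed=10)


def test_random_genome_gc_within_binomial_bound():
    n = 100_000
    g = random_genome(n, gc=0.5, seed=4)
    gc = (g.count("G") + g.count("C")) / n
    sd = math.sqrt(0.25 / n)
    assert abs(gc - 0.5) <= 3 * sd


# ---------------------------------------------------------------------------
# planting variants
# ---------------------------------------------------------------------------

def test_plant_snps_zero_is_identity():
    g = random_genome(2000, seed=1)
    alt, truth = plant_snps(g, 0, 15)
    assert alt == g and truth == []


def test_plant_snps_construction():
    k = 15
    g = random_genome(20_000, seed=2)
    alt, truth = plant_snps(g, 10, k, seed=5)
    assert len(truth) == 10
    diffs = [i for i, (x, y) in enumerate(zip(g, alt)) if x != y]
    assert diffs == [t.position for t in truth]
    positions = [t.position for t in truth]
    assert all(
        abs(p - q) >= 2 * k for p, q in zip(positions, positions[1:])
    )
    for t in truth:
        assert g[t.position] == t.detail["ref"]
        assert alt[t.position] == t.detail["alt"]
        assert t.detail["alt_window"] == alt[t.position - k + 1 : t.position + k]


def test_plant_snps_windows_unique_by_census():
    k = 11
    g = random_genome(8000, seed=6)
    alt, truth = plant_snps(g, 5, k, seed=7)
    # exhaustive scan: each truth alt window occurs exactly once across
    # both haplotypes (canonically)
    both = [g, alt]
    for t in truth:
        win = t.detail["alt_window"]
        hits = sum(
            hap[i : i + 2 * k - 1] in (win, reverse_complement(win))
            for hap in both
            for i in range(len(hap) - (2 * k - 1) + 1)
        )
        assert hits == 1


def test_plant_snps_capacity_error():
    g = random_genome(200, seed=1)
    with pytest.raises((ValueError, RuntimeError)):
        plant_snps(g, 50, 15, seed=1)


def test_plant_inversions_construction():
    k = 13
    g = random_genome(6000, seed=3)
    alt, truth = plant_inversions(g, 3, 60, 120, k, seed=3)
    assert len(truth) == 3
    for t in truth:
        s, e = t.detail["start"], t.detail["end"]
        assert alt[s:e] == reverse_complement(g[s:e])
        # each breakpoint word occurs in exactly one haplotype
        for key in ("au", "vb", "avp", "upb"):
            word = t.detail[key]
            hits = sum(
                (word in hap) or (reverse_complement(word) in hap)
                for hap in (g, alt)
            )
            assert hits == 1
    # double inversion restores the reference
    restored = list(alt)
    for t in truth:
        s, e = t.detail["start"], t.detail["end"]
        restored[s:e] = reverse_complement(alt[s:e])
    assert "".join(restored) == g


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def test_reads_error_free_are_substrings():
    g = random_genome(2000, seed=8)
    cfg = ReadSimConfig(coverage=5.0, read_len=100, err_rate=0.0, seed=1)
    reads = list(simulate_reads(g, cfg, "s"))
    assert len(reads) == math.ceil(5.0 * 2000 / 100)
    rc = reverse_complement(g)
    for rec in reads:
        assert rec.sequence in g or rec.sequence in rc
        assert len(rec.quality) == 100


def test_reads_full_length_coverage_one():
    g = random_genome(300, seed=12)
    cfg = ReadSimConfig(coverage=1.0, read_len=300, err_rate=0.0, seed=2)
    reads = list(simulate_reads(g, cfg, "s"))
    assert len(reads) == 1
    assert reads[0].sequence in (g, reverse_complement(g))


def test_reads_error_rate_binomial_bound():
    g = random_genome(10_000, seed=13)
    cfg = ReadSimConfig(coverage=10.0, read_len=100, err_rate=0.01, seed=3)
    n_bases = 0
    n_mismatch = 0
    rc = reverse_complement(g)
    # align each read back to its (known-length) source by brute scan is
    # costly; instead compare against an error-free rerun of the generator
    clean = list(simulate_reads(g, ReadSimConfig(10.0, 100, 0.0, 3), "s"))
    noisy = list(simulate_reads(g, cfg, "s"))
    for a, b in zip(clean, noisy):
        n_bases += len(a.sequence)
        n_mismatch += sum(x != y for x, y in zip(a.sequence, b.sequence))
    p = n_mismatch / n_bases
    sd = math.sqrt(0.01 * 0.99 / n_bases)
    assert abs(p - 0.01) <= 3 * sd


def test_reads_deterministic_per_seed():
    g = random_genome(1000, seed=14)
    cfg = ReadSimConfig(coverage=3.0, read_len=80, err_rate=0.02, seed=9)
    r1 = [(r.identifier, r.sequence) for r in simulate_reads(g, cfg, "s")]
    r2 = [(r.identifier, r.sequence) for r in simulate_reads(g, cfg, "s")]
    assert r1 == r2


def test_read_len_exceeding_genome_rejected():
    with pytest.raises(ValueError):
        list(simulate_reads("ACGTACGT", ReadSimConfig(1.0, 100, 0.0, 0), "s"))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _snp_truth(k=5):
    ref_w = "ACGTACCGG"  # 2k-1 = 9 bases
    alt_w = ref_w[:4] + "G" + ref_w[5:]
    return TruthRecord(
        "snp", 4, {"ref": ref_w[4], "alt": "G", "ref_window": ref_w, "alt_window": alt_w}
    )


def test_evaluate_snps_exact_match_and_edges():
    t = _snp_truth()
    bub = SnpBubble(*sorted((t.detail["ref_window"], t.detail["alt_window"])))
    recall, precision, matched = evaluate_snps([bub], [t], 5)
    assert (recall, precision, matched) == (1.0, 1.0, [0])
    recall, precision, matched = evaluate_snps([], [t], 5)
    assert (recall, precision) == (0.0, 1.0)
    recall, precision, _ = evaluate_snps([bub], [], 5)
    assert (recall, precision) == (1.0, 0.0)


def test_evaluate_snps_dedup_and_rc_invariance():
    t = _snp_truth()
    pa, pb = sorted((t.detail["ref_window"], t.detail["alt_window"]))
    bub = SnpBubble(pa, pb)
    rc_pair = sorted((reverse_complement(pa), reverse_complement(pb)))
    bub_rc = SnpBubble(*rc_pair)
    recall, precision, _ = evaluate_snps([bub, bub_rc, bub], [t], 5)
    assert recall == 1.0 and precision == 1.0


def test_evaluate_inversions_orbit_invariance():
    g = random_genome(700, seed=20)
    alt, truth = plant_inversions(g, 1, 60, 80, 9, seed=2)
    d = truth[0].detail
    k = 9
    a, u = d["au"][:k], d["au"][k:]
    v, b = d["vb"][:k], d["vb"][k:]
    rc = reverse_complement
    for variant in [(a, u, v, b), (a, rc(v), rc(u), b), (rc(b), u, v, rc(a))]:
        ev = InversionEvent(*variant)
        recall, precision = evaluate_inversions([ev], truth)
        assert (recall, precision) == (1.0, 1.0)
    assert evaluate_inversions([], truth) == (0.0, 1.0)


def test_truth_tsv_roundtrip(tmp_path):
    g = random_genome(5000, seed=30)
    alt, truth = plant_snps(g, 3, 11, seed=1)
    alt2, truth_inv = plant_inversions(alt, 1, 50, 80, 11, seed=1)
    allt = truth + truth_inv
    p = tmp_path / "truth.tsv"
    write_truth_tsv(allt, str(p))
    back = read_truth_tsv(str(p))
    assert [(t.kind, t.position, t.detail) for t in back] == [
        (t.kind, t.position, t.detail) for t in allt
    ]
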