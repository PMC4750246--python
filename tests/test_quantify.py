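import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kmervar.kmer_index import reverse_complement
from kmervar.quantify import (
    AlleleCounts,
    map_read,
    phi_score,
    quantify_bubbles,
    rank_bubbles,
)
from kmervar.seq_io import SequenceRecord
from kmervar.simulate import ReadSimConfig, plant_snps, random_genome, simulate_reads
from kmervar.snp_caller import SnpBubble, find_snp_bubbles, extend_flanks

from conftest import graph_from_seqs


def brute_map(read, target, center, max_mismatch, k):
    """Oracle: scan every offset on both strands, ungapped."""
    for oriented in (read, reverse_complement(read)):
        for off in range(-len(oriented) + 1, len(target)):
            s, e = max(0, off), min(len(target), off + len(oriented))
            if e - s < k:
                continue
            matches = [oriented[t - off] == target[t] for t in range(s, e)]
            mism = matches.count(False)
            # anchor: a run of >= k consecutive matches
            run = best = 0
            for m in matches:
                run = run + 1 if m else 0
                best = max(best, run)
            if best >= k and mism <= max_mismatch and s <= center < e:
                return True
    return False


def test_map_read_identity_and_center_rule():
    target = "CAGCGTCATAAGTCTTTATG"
    assert map_read(target, target, center=10, max_mismatch=0, k=5)
    # read covering only the left flank never covers the center
    assert not map_read(target[:8], target, center=10, max_mismatch=1, k=5)


def test_map_read_reverse_strand():
    target = "CAGCGTCATAAGTCTTTATG"
    assert map_read(reverse_complement(target), target, center=10, max_mismatch=0, k=5)


def test_map_read_agrees_with_offset_oracle():
    rng = random.Random(99)
    k = 5
    for _ in range(200):
        target = "".join(rng.choice("ACGT") for _ in range(rng.randint(8, 30)))
        if rng.random() < 0.5:
            start = rng.randrange(0, max(1, len(target) - 6))
            read = list(target[start : start + rng.randint(6, 15)])
            if read and rng.random() < 0.7:
                i = rng.randrange(len(read))
                read[i] = rng.choice("ACGT")
            read = "".join(read)
        else:
            read = "".join(rng.choice("ACGT") for _ in range(rng.randint(6, 15)))
        if len(read) < k:
            continue
        center = rng.randrange(len(target))
        mm = rng.choice([0, 1, 2])
        assert map_read(read, target, center, mm, k) == brute_map(
            read, target, center, mm, k
        )


def _toy_bubble():
    g = graph_from_seqs(["CTGACCT", "CTGTCCT"], k=4)
    (bub,) = find_snp_bubbles(g)
    return bub


def test_quantify_constructed_counts():
    bub = _toy_bubble()
    reads_a = [SequenceRecord(f"a{i}", bub.path_a) for i in range(10)]
    reads_b = [SequenceRecord(f"b{i}", bub.path_b) for i in range(10)]
    quantify_bubbles([bub], [("s1", reads_a), ("s2", reads_b)], max_mismatch=0, k=4)
    assert bub.counts.table.tolist() == [[10, 0], [0, 10]]


def test_quantify_flank_only_read_counted_nowhere():
    k = 11
    genome = random_genome(600, seed=40)
    alt, _ = plant_snps(genome, 1, k, seed=3)
    g = graph_from_seqs([genome, alt], k=k)
    (bub,) = find_snp_bubbles(g)
    extend_flanks(g, bub)
    flank_read = SequenceRecord("f", bub.left_contig[-30:])
    quantify_bubbles([bub], [("s", [flank_read])], max_mismatch=1, k=k)
    assert bub.counts.table.sum() == 0


def test_quantify_ambiguous_read_dropped():
    bub = _toy_bubble()
    # the shared 3-base prefix extended ambiguously: equal distance to both
    read = SequenceRecord("x", bub.path_a[:3] + "N" + bub.path_a[4:])
    # N mismatches both alleles equally at the center -> dropped
    quantify_bubbles([bub], [("s", [read])], max_mismatch=2, k=3)
    assert bub.counts.table.sum() == 0


def test_quantify_heterozygous_coverage_split():
    k = 21
    genome = random_genome(4000, seed=8)
    alt, _ = plant_snps(genome, 1, k, seed=8)
    g = graph_from_seqs([genome, alt], k=k)
    (bub,) = find_snp_bubbles(g)
    extend_flanks(g, bub)
    cfg = ReadSimConfig(coverage=15.0, read_len=80, err_rate=0.0, seed=77)
    reads = list(simulate_reads(genome, cfg, "ref")) + list(
        simulate_reads(alt, ReadSimConfig(15.0, 80, 0.0, 78), "alt")
    )
    quantify_bubbles([bub], [("het", reads)], max_mismatch=1, k=k)
    a, b = int(bub.counts.table[0, 0]), int(bub.counts.table[1, 0])
    # each allele sampled ~ Poisson(lam) supporting reads; check central 99%
    lam = 15.0 * (80 - 21) / 80
    lo, hi = lam - 3 * math.sqrt(lam), lam + 3 * math.sqrt(lam)
    assert lo <= a <= hi and lo <= b <= hi


# ---------------------------------------------------------------------------
# phi score
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "table,expected",
    [
        ([[10, 0], [0, 10]], 1.0),
        ([[5, 5], [5, 5]], 0.0),
        ([[8, 2], [2, 8]], math.sqrt(7.2 / 20)),  # chi2 = 4*(3^2)/5 = 7.2
        ([[0, 0], [0, 0]], 0.0),
        ([[3, 4], [0, 0]], 0.0),  # empty allele row
    ],
)
def test_phi_examples(table, expected):
    assert phi_score(np.array(table)) == pytest.approx(expected)


def test_phi_rejects_negative():
    with pytest.raises(ValueError):
        phi_score(np.array([[1, -1], [0, 2]]))


@given(
    st.lists(
        st.tuples(st.integers(0, 50), st.integers(0, 50)),
        min_size=2,
        max_size=6,
    )
)
@settings(max_examples=200, deadline=None)
def test_phi_range_and_invariances(cols):
    table = np.array(cols, dtype=np.int64).T  # 2 x S
    phi = phi_score(table)
    assert 0.0 <= phi <= 1.0
    # row swap and column permutation leave phi unchanged
    assert phi_score(table[::-1]) == pytest.approx(phi)
    perm = np.random.default_rng(0).permutation(table.shape[1])
    assert phi_score(table[:, perm]) == pytest.approx(phi)
    # integer scaling leaves phi unchanged
    assert phi_score(3 * table) == pytest.approx(phi)


@given(st.tuples(*[st.integers(0, 40)] * 4))
@settings(max_examples=200, deadline=None)
def test_phi_two_sets_closed_form(abcd):
    a, b, c, d = abcd
    table = np.array([[a, b], [c, d]])
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    expected = abs(a * d - b * c) / math.sqrt(denom) if denom else 0.0
    assert phi_score(table) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def test_rank_bubbles_order_and_ties():
    def mk(i, phi):
        bub = SnpBubble("ACGCACC", "ACGTACC", bubble_id=i)
        bub.phi = phi
        return bub

    bubbles = [mk(0, 0.2), mk(1, 0.9), mk(2, 0.2)]
    ranked = rank_bubbles(bubbles)
    assert [b.bubble_id for b in ranked] == [1, 0, 2]
    # all-equal phis keep id order
    ranked = rank_bubbles([mk(2, 0.5), mk(0, 0.5), mk(1, 0.5)])
    assert [b.bubble_id for b in ranked] == [0, 1, 2]


def test_rank_is_permutation():
    rng = random.Random(1)

    def mk(i):
        bub = SnpBubble("ACGCACC", "ACGTACC", bubble_id=i)
        bub.phi = rng.random()
        return bub

    bubbles = [mk(i) for i in range(50)]
    ranked = rank_bubbles(bubbles)
    assert sorted(b.bubble_id for b in ranked) == list(range(50))
    phis = [b.phi for b in ranked]
    assert phis == sorted(phis, reverse=True)
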