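import json

import pytest

from kmervar.kmer_index import KmerSpec, count_kmers, reverse_complement
from kmervar.seq_io import SequenceRecord
from kmervar.simulate import ReadSimConfig, plant_snps, random_genome, simulate_reads
from kmervar.targeted_asm import (
    build_neighborhood_graph,
    extend_linear,
    make_starter,
    read_graph_json,
    validate_starter,
    validate_graph_doc,
    write_graph_json,
)

from conftest import graph_from_seqs


K = 15


def _tables(readsets, k=K):
    return [(name, count_kmers([recs], KmerSpec(k))) for name, recs in readsets]


def test_starter_fraction_verbatim_and_random():
    genome = random_genome(1000, seed=1)
    g = graph_from_seqs([genome], k=K)
    st = make_starter(SequenceRecord("s", genome[300:400]), g.solid)
    assert st.solid_fraction == 1.0
    assert validate_starter(st, g.solid)
    unrelated = make_starter(SequenceRecord("u", random_genome(100, seed=99)), g.solid)
    assert unrelated.solid_fraction < 0.1
    assert not validate_starter(unrelated, g.solid)


def test_starter_one_snp_fraction_analytic():
    genome = random_genome(2000, seed=2)
    g = graph_from_seqs([genome], k=K)
    s = list(genome[500:600])
    s[50] = "ACGT"[("ACGT".index(s[50]) + 1) % 4]
    st = make_starter(SequenceRecord("m", "".join(s)), g.solid)
    n_windows = 100 - K + 1
    expected = 1 - min(K, n_windows) / n_windows
    assert st.solid_fraction == pytest.approx(expected)


def test_starter_shorter_than_k_rejected():
    g = graph_from_seqs([random_genome(200, seed=3)], k=K)
    with pytest.raises(ValueError):
        make_starter(SequenceRecord("x", "ACGT"), g.solid)


def test_extend_linear_reconstructs_genome():
    genome = random_genome(1200, seed=4)
    g = graph_from_seqs([genome], k=K)
    st = make_starter(SequenceRecord("s", genome[500:560]), g.solid)
    left, right = extend_linear(g, st)
    assert left + st.sequence + right == genome


def test_extend_linear_stops_at_snp_fork():
    genome = random_genome(3000, seed=5)
    alt, truth = plant_snps(genome, 1, K, seed=1)
    pos = truth[0].position
    g = graph_from_seqs([genome, alt], k=K)
    start = pos - 300
    st = make_starter(SequenceRecord("s", genome[start : start + 60]), g.solid)
    left, right = extend_linear(g, st)
    # rightward extension stops at the SNP fork: the first divergent
    # window starts at pos-K+1, so the extension ends just before it
    end = start + 60 + len(right)
    assert end == pos  # last included base is the one before the SNP site
    assert (left + st.sequence + right) in genome


def test_extend_linear_max_len_zero():
    genome = random_genome(400, seed=6)
    g = graph_from_seqs([genome], k=K)
    st = make_starter(SequenceRecord("s", genome[100:160]), g.solid)
    assert extend_linear(g, st, max_len=0) == ("", "")


def test_extend_linear_unsolid_terminal_warns():
    genome = random_genome(400, seed=7)
    g = graph_from_seqs([genome], k=K)
    st = make_starter(
        SequenceRecord("s", genome[100:160] + random_genome(K, seed=55)), g.solid
    )
    with pytest.warns(UserWarning, match="right terminal"):
        left, right = extend_linear(g, st)
    assert right == ""


def test_neighborhood_graph_repeat_free():
    genome = random_genome(900, seed=8)
    readsets = [("s1", [SequenceRecord("g", genome)])]
    g = graph_from_seqs([genome], k=K)
    st = make_starter(SequenceRecord("s", genome[400:460]), g.solid)
    ngraph = build_neighborhood_graph(g, st, _tables(readsets))
    assert len(ngraph.nodes) == 1  # starter node swallows the whole genome
    assert ngraph.nodes[0].is_starter
    assert ngraph.nodes[0].seq == genome
    assert ngraph.nodes[0].cov[0] == pytest.approx(1.0)


def test_neighborhood_graph_snp_bubble_and_coverage_separation():
    genome = random_genome(4000, seed=9)
    alt, truth = plant_snps(genome, 1, K, seed=2)
    pos = truth[0].position
    cfg_r = ReadSimConfig(coverage=20.0, read_len=80, err_rate=0.0, seed=1)
    cfg_a = ReadSimConfig(coverage=20.0, read_len=80, err_rate=0.0, seed=2)
    reads_ref = list(simulate_reads(genome, cfg_r, "ref"))
    reads_alt = list(simulate_reads(alt, cfg_a, "alt"))
    readsets = [("ref", reads_ref), ("alt", reads_alt)]
    g = graph_from_seqs([r.sequence for r in reads_ref + reads_alt], k=K, c=2)
    start = pos - 200
    st = make_starter(SequenceRecord("s", genome[start : start + 60]), g.solid)
    ngraph = build_neighborhood_graph(g, st, _tables(readsets))
    # the two allele branches appear as parallel nodes sharing the parent
    from collections import defaultdict

    children = defaultdict(list)
    for a, b in ngraph.edges:
        children[a].append(b)
    bubbles = [kids for kids in children.values() if len(kids) == 2]
    assert bubbles, "expected a two-node parallel bubble"
    kids = bubbles[0]
    covs = {tuple(round(c, 1) for c in ngraph.nodes[n].cov) for n in kids}
    # one branch is covered by the ref sample only, the other by alt only
    for n in kids:
        ref_cov, alt_cov = ngraph.nodes[n].cov
        assert (ref_cov > 3 and alt_cov < 1) or (alt_cov > 3 and ref_cov < 1)


def test_graph_json_roundtrip_and_schema(tmp_path):
    genome = random_genome(2500, seed=10)
    alt, _ = plant_snps(genome, 1, K, seed=3)
    readsets = [("s1", [SequenceRecord("g", genome), SequenceRecord("h", alt)])]
    g = graph_from_seqs([genome, alt], k=K)
    st = make_starter(SequenceRecord("s", genome[100:180]), g.solid)
    ngraph = build_neighborhood_graph(g, st, _tables(readsets))
    p = tmp_path / "graph.json"
    write_graph_json(ngraph, str(p))
    doc = json.loads(p.read_text())
    validate_graph_doc(doc)  # shipped-schema invariants hold
    back = read_graph_json(str(p))
    assert [(n.node_id, n.seq, n.is_starter) for n in back.nodes] == [
        (n.node_id, n.seq, n.is_starter) for n in ngraph.nodes
    ]
    assert back.edges == ngraph.edges


def test_graph_validation_rejects_bad_docs():
    with pytest.raises(ValueError):
        validate_graph_doc({"k": 5, "nodes": [], "edges": []})
    with pytest.raises(ValueError):
        validate_graph_doc(
            {
                "k": 5,
                "starter": 0,
                "nodes": [
                    {"id": 0, "seq": "ACGTA", "cov": [1.0], "is_starter": False}
                ],
                "edges": [],
            }
        )


def test_graph_independent_of_read_order():
    genome = random_genome(2000, seed=11)
    alt, _ = plant_snps(genome, 1, K, seed=4)
    reads = [SequenceRecord(f"r{i}", s) for i, s in enumerate((genome, alt))]
    g1 = graph_from_seqs([genome, alt], k=K)
    g2 = graph_from_seqs([alt, genome], k=K)
    st1 = make_starter(SequenceRecord("s", genome[50:120]), g1.solid)
    st2 = make_starter(SequenceRecord("s", genome[50:120]), g2.solid)
    t1 = _tables([("s1", reads)])
    t2 = _tables([("s1", list(reversed(reads)))])
    ng1 = build_neighborhood_graph(g1, st1, t1)
    ng2 = build_neighborhood_graph(g2, st2, t2)
    assert [(n.seq, n.cov) for n in ng1.nodes] == [(n.seq, n.cov) for n in ng2.nodes]
    assert ng1.edges == ng2.edges
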