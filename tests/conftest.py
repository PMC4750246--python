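import warnings

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from kmervar.dbg import DeBruijnGraph, build_graph
from kmervar.kmer_index import KmerSpec, build_solid_set, count_kmers
from kmervar.seq_io import SequenceRecord


def graph_from_seqs(seqs, k, c=1):
    """Build a de Bruijn graph from raw sequence strings."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # even-k toy graphs
        table = count_kmers([list(seqs)], KmerSpec(k))
        solid = build_solid_set(table, c)
        return build_graph(solid)


def records(*seqs, prefix="r"):
    return [SequenceRecord(f"{prefix}{i}", s) for i, s in enumerate(seqs)]


@pytest.fixture
def fig_toy_graph() -> DeBruijnGraph:
    """The classic two-read bubble toy: one SNP, k=4, c=1."""
    return graph_from_seqs(["CTGACCT", "CTGTCCT"], k=4)


@pytest.fixture(autouse=True)
def _silence_even_k_warning():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
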