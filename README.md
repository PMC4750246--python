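# kmervar

Reference-free variant discovery and read-set comparison from raw
sequencing reads, built on a single shared kernel: the de Bruijn graph
over *solid* canonical k-mers, realized implicitly through membership
queries against an exact k-mer set optionally fronted by a bloom
filter.

`kmervar` is aimed at people analysing short-read data for organisms
without a (good) reference genome — population genomicists calling
SNPs in non-model species, microbiologists screening isolates for
structural rearrangements, metagenomics groups triaging many samples
before assembly.  No alignment and no assembly is performed: variants
are recognized directly as topological motifs in the graph of the raw
reads.

## The model

Let a *k-mer* be a length-k DNA word and its *canonical* form the
lexicographic minimum of the word and its reverse complement.  A k-mer
is *solid* when its canonical form occurs at least *c* times across
the pooled input read sets.  The de Bruijn graph has the solid k-mers
as vertices and their exact (k−1)-overlaps as arcs; neighbors are
computed by at most four membership queries, so the graph is never
stored.

Four methods read motifs off this graph:

- **SNP bubbles** — an isolated SNP (no second polymorphism within its
  (2k−1)-window) generates a pair of vertex-disjoint k-vertex paths
  spelling two sequences of length 2k−1 that differ at exactly the
  center position.  After detection, reads are mapped back (ungapped,
  anchored by a shared k-mer) onto each allele to produce per-sample
  allele counts, and bubbles are ranked by the **phi score**
  √(χ²/N) ∈ [0,1] of the 2×S allele-by-sample contingency table —
  a normalized chi-squared statistic that is largest for SNPs that
  discriminate between samples.
- **Inversion breakpoints** — an inverted segment I between flanks a
  and b (aIb in one genome, aI′b in the other, with u, v the first and
  last k-mers of I) leaves four 2k breakpoint words au, vb, av′, u′b
  that join a, u, v, b in a pseudo-cycle of two k-forks.  A local
  dissimilarity guard (Hamming(u, v′) ≥ 3 by default) suppresses the
  motif's false positives from repeats and palindromes.
- **Targeted assembly** — user-supplied *starter* sequences are
  validated against the solid set, extended linearly until the graph
  offers two choices, and surrounded by a JSON neighborhood graph of
  compacted unitigs annotated with per-sample coverage, in which SNPs
  appear as parallel node pairs.
- **Read-set comparison** — each set is k-mer-indexed; a read is
  *similar to* a set when ≥ t of its k-mers are in the index.  The
  per-read bits form compact vectors supporting logical set algebra;
  directed percentages fold into a symmetric similarity matrix and an
  average-linkage dendrogram.

A bundled simulator generates random genomes, plants isolated SNPs and
inversions with structurally recoverable (unique, unambiguous)
breakpoint windows, simulates substitution-error shotgun reads, and
scores caller output against the planted truth.

## Worked example

Simulate a 50 kb genome pair with 10 planted SNPs, call and quantify:

```bash
kmervar simulate -o demo --length 50000 --snps 10 -k 31 \
    --coverage 30 --read-len 100 --seed 4
kmervar snp -r demo.ref.fastq -r demo.alt.fastq -k 31 -c 2 -o calls
kmervar eval --truth demo.truth.tsv --bubbles calls.bubbles.fa -k 31 -o metrics.tsv
```

The log reports the kernel and call counts:

```
[kernel] 50278 distinct k-mers, 50271 solid (c=2)
[snp] 10 bubbles
```

`calls.counts.tsv` ranks the bubbles by phi with per-allele per-sample
supporting-read counts (here every SNP separates the two haplotype
samples perfectly, so phi = 1):

```
bubble_id  phi       C_A_demo.ref  C_B_demo.ref  C_A_demo.alt  C_B_demo.alt
0          1.000000  26            0             0             32
1          1.000000  0             35            43            0
```

`calls.bubbles.fa` holds each bubble as two consecutive records —
allele path plus its shared flanking contigs, with the coverage and
phi annotations inline:

```
>SNP_0|P_A|left=262|right=7202|C_demo.ref=26|C_demo.alt=0|phi=1.000000
TAAGATGGCTAAGACGCGTATAGACTAGGAAGTTACC...
```

and `metrics.tsv` confirms recovery of the planted truth:

```
kind  recall  precision  n_truth  n_predicted
snp   1.0000  1.0000     10       10
```

The other pipelines follow the same shape: `kmervar inv` writes four
2k breakpoint records per inversion event, `kmervar target` writes an
extended FASTA plus a JSON graph per starter (schema in
`src/kmervar/schemas/`), and `kmervar compare` writes directed and
symmetric similarity TSVs, per-pair bit-vector files and a newick
dendrogram.

## File formats

- Input reads: FASTA or FASTQ, plain or gzipped, auto-detected by
  content.  Records are treated as unordered pools; qualities are
  carried but never interpreted.
- Solid sets persist to a small binary file (`KVSS1`: magic, k, c,
  count, packed k-mers sorted ascending).
- Shared-read bit vectors persist as `KVBV1`: magic, k, t, set names,
  read count, packed bits.
- All text outputs start with `#` header lines echoing the tool
  version and full configuration; coordinates are 0-based half-open.
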