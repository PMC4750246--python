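# Methods

This note records the models, parameter choices, numerical decisions
and known limitations behind `kmervar`, in the order data flows
through the package.

## The k-mer kernel

All methods share one membership structure: the set of canonical
k-mers occurring at least `c` times in the pooled input reads
("solid" k-mers).  k-mers are packed 2 bits per base into a 64-bit
word, capping k at 31; `k` defaults to 31 and odd k is recommended
(and warned about otherwise) because even k admits
self-reverse-complement k-mers, which merge the two strands of a locus
into one vertex and create spurious forks (the package's own unit
tests demonstrate this on small palindrome-rich sequences).

Counting is vectorized: each read's windows are packed and
canonicalized as numpy arrays, pooled, and reduced with a single sort;
counts saturate at 2¹⁶−1 since solidity thresholds are small.  The
solidity threshold `c` defaults to 3 — enough to drop singleton and
doubleton error k-mers at typical (≥ 20×) coverages while keeping
true k-mers, and exposed everywhere for calibration against coverage
(the acceptance runs use c = 2 for error-free 30× data and c = 4 for
1%-error 40× data, roughly c ≈ coverage/10).

Two membership structures exist side by side.  The **exact solid set**
(a hash set over the packed k-mers, plus an "oriented" set holding
both orientations so graph queries skip reverse-complement
computation) is the membership truth for every algorithm.  The
**bloom filter** (m = 16 bits per element, h = 7 hash addresses by
default, double hashing g_i = h1 + i·h2 from two splitmix64-finalized
64-bit hashes) is an optional prefilter: queries hit it first and
positives are confirmed exactly.  Its false-positive rate follows
(1 − e^(−hn/m))^h ≈ 7·10⁻⁴ at the defaults, verified empirically
within a factor two; it never produces false negatives.  Keeping
exactness as the baseline was a deliberate trade: correctness of the
callers is then independent of filter calibration, and the bloom path
remains available for memory-footprint experiments.

## The implicit de Bruijn graph

Vertices are solid canonical k-mers; arcs are exact (k−1)-overlaps.
Neighbors are computed by appending/prepending each of the four bases
and testing membership, so the graph is never materialized.  Traversal
works on *oriented* k-mers with strand-neutral membership — the
bidirected graph induced by double-stranded data, at no extra storage.

Unitig extension stops at a branch, a dead end, a revisited vertex
(loop guard), or `max_len` (default 10,000 bases — flanks are context,
not assemblies).  Two stop rules are used deliberately: flanking
contigs for variant calls use the standard both-sides-unique rule
(the next vertex must also have a unique predecessor), which prevents
chimeric flanks at bubble entrances; targeted linear extension cuts
only when the walk itself faces two or more choices, matching the
"cut at the first fork" contract of seed-anchored assembly.

## SNP bubbles

An isolated SNP yields two k-vertex paths spelling (2k−1)-sequences
that differ at exactly the center.  Detection seeds on pairs of solid
oriented k-mers identical except at their last base (found by one sort
of the oriented k-mer array by (k−1)-prefix) and extends both paths
simultaneously k−1 steps, requiring every window of both paths solid.

Isolation is enforced purely structurally — the paths must agree
everywhere but the center; nearby SNPs simply fail extension.  Two
extension modes exist:

- **strict** (default): each step must admit exactly one base, and the
  candidate windows must keep the two paths vertex-disjoint at the
  canonical level (a window whose canonical form is already on either
  path is inadmissible).  The disjointness clause is part of the
  bubble definition — two vertex-disjoint paths — and matters in
  practice: in small or strand-symmetric graphs a path can otherwise
  step onto the reverse complement of its partner's vertices, which
  both fabricates branching (killing true bubbles) and fabricates
  bubbles.
- **relaxed**: enumerates every admissible completion, with no
  disjointness or uniqueness requirement.  This mode implements the
  plain enumeration contract and is the one checked against an
  independent exhaustive-DFS oracle in the tests.

Output pairs are deduplicated to a reverse-complement-canonical
representative (the lexicographically smaller of the sorted pair and
its reverse-complemented sorted pair), so the caller is strand
invariant by construction.  Each bubble may carry flanking unitig
contigs entered through the unique shared neighbor of the two path
ends.

## Read map-back and the phi score

Reads are mapped back ungapped onto each allele's flanked sequence,
on both strands, anchored by at least one exact shared k-mer; a
placement supports an allele only if it covers the variant position
with at most `max_mismatch` mismatches (default 1).  In practice an
inverted index over the target k-mers proposes candidate placements,
which is exactly the anchor condition.  A read whose best placements
tie between the two alleles carries no allelic information and is
counted for neither — dropping rather than splitting avoids
fractional counts; the policy is stated in the output header.

The phi score of the resulting 2×S table is √(χ²/N) (Cramér's V for a
two-row table), with zero-marginal columns skipped and degenerate
tables (empty, one-sided) scored 0.  "Normalized chi-squared in
[0, 1]" admits more than one reading; this one was chosen because it
reduces to the absolute classical phi coefficient |ad−bc|/√((a+b)(c+d)(a+c)(b+d))
for S = 2, is exactly invariant under integer scaling of the table,
and needs no distributional assumptions.  Bubbles are ranked by
descending phi, ties broken by ascending bubble id for determinism.

## Inversion breakpoints

An inverted segment I between flanks a, b leaves the four 2k
breakpoint words au, vb, av′, u′b (u, v the first and last k-mers of
I; ′ denotes reverse complement).  The search: every solid oriented
k-mer with ≥ 2 successors is a candidate a; its solid right-extensions
of length k (abandoned beyond `max_paths` = 100 partial paths, a bound
against repeat blowup) provide candidates for u and, reverse
complemented, for v; candidate b's are the intersection of the
extension ends of v and of u′.

Three guards shape the output:

- **Repeat/palindrome guard**: Hamming(u, v′) ≥ `min_fork_distance`
  (default 3).  Exact repeats and palindromes produce the motif
  without any inversion; a local dissimilarity test is the natural
  defence, with u = v′ flagged `palindromic` when the guard is
  disabled.  (With the guard off, every genomic 2k word trivially
  satisfies the degenerate u = v′ motif, which is precisely why the
  guard defaults on.)
- **Pseudo-cycle non-degeneracy**: b canonically equal to a is
  rejected.  When a segment and its reverse complement both occur in
  the pooled data (which is the defining situation!), strand-crossing
  chimeras of the form (a, u, v, a′) satisfy the four-word condition
  without describing any rearrangement.
- **Canonicalization over the full 8-element orbit**: the four
  breakpoint words, taken up to reverse complement, are invariant
  under strand flip, under swapping (u, v) with (v′, u′), and under
  the dual role-exchange (a,u,v,b) → (u′,a′,b′,v′).  Early versions
  canonicalizing only the first two symmetries reported each event
  twice (once in the dual reading); the representative is now the
  lexicographic minimum over all eight equivalent tuples, so events
  with identical breakpoint evidence always collapse.

Only the breakpoint tuple is reported; the inverted segment itself is
not reconstructed (the motif does not determine it uniquely).

## Targeted assembly

A starter is accepted when at least `min_fraction` = 0.7 of its
windows are solid — permissive enough to tolerate a variant or a few
errors inside the starter, strict enough to reject foreign sequence.
Starters failing validation are reported and skipped; no attempt is
made to correct them.  The neighborhood graph explores compacted
unitigs breadth-first from both starter ends up to `max_depth` = 5
branch levels or `max_nodes` = 200 nodes, with successors visited in
base order and re-reached unitigs merged by their start k-mer, making
node ids deterministic and letting bubble branches reconverge on a
shared node.  Node coverage is the mean count of the node's windows in
each sample's count table — a k-mer proxy chosen over read mapping
because it is exact, cheap, and sufficient to color haplotype-specific
branches at this scale.

## Read-set comparison

A read is similar to an indexed set when ≥ t of its (possibly
overlapping) k-mer windows are in the index; t defaults to 2, one
being noise-prone at large k and higher values discarding short
overlaps.  This similarity rule is an interpretation — the package
exposes t and records it in every output.  Directed percentages
pct(A→B) = 100·|similar reads|/|A| fold into
sym(A,B) = 100·(shared(A→B)+shared(B→A))/(|A|+|B|), with
sym(A,A) ≡ 100.  Clustering is average linkage on d = 100 − sym
(scipy), rows ordered by set name so equal-distance merges resolve
deterministically; the tree is emitted as newick via scikit-bio.
Bit vectors computed against a bloom index always contain those
computed against the exact index of the same set (false positives only
add bits) — asserted as a property test.

## The simulator

The simulator defines the conditions under which the callers are
validated: i.i.d. random genomes of configurable GC; isolated SNPs
planted with pairwise separation ≥ 2k, ≥ 2k from the ends, and every
k-mer of both the ref and alt (2k−1)-windows unique across both
haplotypes; inversions of configurable length with flank and terminal
k-mers that are unique, non-palindromic, locally dissimilar
(Hamming(u, v′) ≥ 3), fork-visible (first bases towards u and v′
differ) and free of breakpoint micro-homology (the base before the
segment must not complement the base after it — otherwise the same
rearrangement has two valid coordinate descriptions and hence two
valid breakpoint motifs).  Reads have uniform start positions, fair
strand choice, and i.i.d. substitution errors; there are no indels,
because every implemented caller models substitution-induced motifs
and indel reads would probe machinery out of scope here.

These uniqueness constraints make perfect recall under error-free
saturating coverage a structural guarantee, which is the point: the
evaluation then measures the callers, not luck.  Real data offer no
such guarantees — repeats, close variants, coverage gaps and indels
all degrade the motifs — so perfect scores on simulated data bound,
rather than predict, performance in the field.

All randomness flows through numpy Generators seeded from
(seed, purpose-label) pairs, so pipelines are deterministic per seed
and the streams for genome, variants and each read set are
independent.

## Problem sizes and defaults used in the shipped evaluation

The acceptance script and end-to-end tests run at: 100 kb genomes with
40 SNPs for SNP recovery (30× error-free at c = 2; 40× at 1%
substitution error and c = 4), 50 kb genomes with 10 inversions of
100–500 bp at 30× (k = 21), 10⁵-element bloom calibration, 5 kb
genomes at 5× for the comparison suite, and 20 kb genomes for targeted
assembly.  These sizes exercise every code path at desk scale; the
algorithms contain nothing that is scale-dependent beyond memory for
the k-mer table.

## Known limitations

- No indel or multi-nucleotide variant calling; close SNP pairs
  (within 2k−1) structurally fail the isolated-bubble model.
- Membership is per-k-mer; very high coverage heterogeneity (e.g.
  mixed-abundance metagenomes) needs per-sample solidity, which is not
  implemented.
- The inversion repeat guard is a local Hamming test; diverged repeats
  longer than k can still produce false motifs.
- The bloom-only mode trades exactness for memory and can add false
  arcs; it is intended for footprint experiments, not calling.
- Paired-end information is ignored throughout; read sets are
  unordered pools.
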