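# Methods

## The model

`dispatchmap` decomposes read alignment against a target set *T* into `P`
independent subproblems whose union is provably equivalent to the original
problem for any aligner whose candidate hits require an exact seed match of
length ≥ *l*. The argument has three parts:

1. **Partitioning** assigns every target to exactly one partition, so the
   set of (read, target) alignment pairs is partitioned, not duplicated or
   lost.
2. **Dispatch** queries every *b*-mer of a read against each partition's
   Bloom filter of target *b*-mers, with *b* ≤ *l*. Any alignment the
   aligner could report contains an exact match of length ≥ *l* ≥ *b*, and
   that match contains at least one read *b*-mer present in the partition's
   filter. Bloom filters never return false negatives, so the read is
   dispatched to every partition where it could align. False positives
   dispatch reads to partitions where they do not align; those produce
   unmapped or inferior records that the merge stage drops.
3. **Merging** selects, per read, the best record over all partitions. If
   per-partition record quality equals unpartitioned quality (true for the
   built-in mapper, whose score is the exact-match length, a local
   property), the argmax over the union equals the unpartitioned result.

The one semantic gap is MAPQ: mapping quality is computed *within* a
partition, so a read with equally good loci in two different partitions
gets MAPQ 60 in each, where the unpartitioned aligner would report 0. The
merge policy's `flag_cross_partition_ties` option zeroes MAPQ on
cross-partition score ties for users who want conservative qualities. The
equivalence tests avoid the gap structurally: duplicated sequence
(contig-overlap regions) only arises in graph-linked contigs, and the
graph-aware partitioner keeps linked contigs in one partition.

## Partitioning

Best-fit decreasing with fixed `P` and unbounded bins reduces to
longest-processing-time multiway number partitioning: sort items by
decreasing weight (ties: lexicographically smaller ID first) and assign
each to the least-loaded partition (ties: lowest index). This carries the
classical (4/3 − 1/(3P)) makespan guarantee, which the tests verify
against exhaustive enumeration on small instances. With an adjacency
graph, connected components (computed via networkx) are the items,
weighted by summed member length; components are never split, so a single
dominant component can cap achievable balance — the planner warns, it does
not intervene. Graph nodes missing from the target set are an error
(inconsistent inputs fail loudly); targets missing from the graph are
singleton components.

## Bloom filters

- **Sizing**: m = r × (number of valid b-mer positions, counted before
  canonical deduplication). Counting insert events rather than distinct
  keys matches the r = m/n model used for the false-positive rate and is
  conservative (duplicated b-mers make the realized rate slightly lower
  than the model).
- **k = ⌊r·ln 2⌋**, clamped to ≥ 1. Floor rather than nearest-integer so
  that the default r = 8 yields k = 5; at some r (e.g. 4) floor lands one
  below the true integer argmin, with a marginal FPR cost. The tests
  assert the within-one-unit property rather than exact optimality.
- **Hashing**: double hashing — one keyed 16-byte blake2b digest per key,
  split into two 64-bit words g1, g2; position_i = (g1 + i·g2) mod m.
  blake2b keyed hashing is deterministic across runs and platforms and
  needs no third-party dependency; uniformity is checked by a chi-square
  test. The bit array is a numpy uint8 buffer.
- **Canonicalization**: b-mers are stored and queried as
  min(s, reverse_complement(s)), making the filter strand-symmetric, since
  aligners report both strands. b-mers containing N are skipped on both
  sides (an undefined base cannot seed an exact match).
- **Persistence**: a small magic + JSON header (m, k, b, seed, n_inserted)
  followed by the raw bit array; round-trips exactly.

## Dispatch

b defaults to *l* (largest value satisfying b ≤ *l*; smaller values may be
set explicitly and the constraint is enforced). Dispatch scans all b-mer
positions with stride 1 but stops querying a partition after its first hit
— the result is identical to scanning everything, only cheaper. Reads
dispatched to multiple partitions are physically duplicated into each
partition's read file so partitions stay independently alignable; reads
with no hits are recorded in `discarded.txt` so the merger can emit
unmapped records and conserve the read universe.

Workload note: the model FPR is per query. A read of length L issues
L − b + 1 queries per partition, so the per-read probability of a
false-positive dispatch is ≈ 1 − (1 − F)^(L−b+1) — at the defaults
(F ≈ 2.2%, 100 bp reads, b = 20) a read fans out to most partitions.
This affects only runtime; raising r (bits per element) shrinks it
exponentially.

## Built-in aligner

Exact-match seed-and-extend: every l-mer occurrence of the targets is
indexed under its canonical key with strand; each read l-mer's hits are
extended to the maximal exact run (one extension per (target, strand,
diagonal) unless a later seed falls outside every interval already
extended there, which handles multiple match segments on one diagonal).
The longest match wins; ties break by leftmost read offset, then target
input order, then smaller target position, then forward strand — fully
deterministic. MAPQ is 60 when the maximal length is achieved at exactly
one (target, position, strand) and 0 otherwise; the match length is
written as the `AS` tag, which the merger uses to break equal-MAPQ ties.
Unmatched flanks are soft-clipped (S) so SEQ survives for the merger.
This mapper is deliberately not a Smith–Waterman: the package's
contribution is the partition/dispatch/merge framework, and an exact
mapper exercises it fully; production alignment goes through the external
adapter templates (`bwa`, `bowtie2`, `novoalign` presets), which run
index-then-align command sequences with token-wise placeholder
substitution (paths with spaces stay single argv entries).

## Merge

Records are grouped per read across partition streams; the ranking is
(MAPQ, AS, then partition index, reference, position, strand). "Best
quality" had to be defined — SAM does not define it — and (MAPQ, then AS)
is the most portable choice across aligners. Multi mode emits up to N
distinct records (distinctness key: reference, position, strand, CIGAR),
secondary-flagging all but the first. Output order is first appearance
scanning streams in partition-index order, then discarded reads:
deterministic and independent of stream arrival order. An optional
expected-ID list turns a vanished read into a hard accounting error.

## Synthetic data

The generator emulates the draft-assembly use case: an i.i.d. uniform
A/C/G/T genome; contigs tiling it at random breakpoints with a fixed
overlap between consecutive contigs and an adjacency edge per overlap
(optionally withheld with some probability to create multiple components);
reads drawn uniformly over all valid (contig, offset) starts — i.e.
contigs weighted by valid start count — with Bernoulli(½) strand and
independent substitution errors. Defaults are a 100 kb genome, 8 contigs
with 100 bp overlaps, and 10,000 error-free 100 bp reads; the pipeline
test suites also use a 4-chromosome variant (four independent genomes,
each a 3-contig graph component) and 0.5–1% error rates. Substitutions
only, no indels: the built-in aligner is exact-match, so an indel read
would merely be soft-clipped and would exercise nothing new.

What the generator does *not* model: real base-composition bias, repeats
(beyond chance k-mer collisions), quality-score structure, paired-end
inserts, and indels. Passing the equivalence suite therefore shows the
framework preserves whatever the plugged-in aligner would report — it does
not certify aligner sensitivity on real, repeat-rich genomes, where
cross-partition MAPQ ties (above) are the known caveat.

## Problem sizes and numerics

The acceptance-style suites run at the scales the guarantees are stated
for: filter calibration with 10⁵ inserted and 10⁵ queried random 20-mers
(empirical rate within 3 binomial σ of the model); dispatch recall and
pipeline equivalence on the 100 kb / 8-contig / 10⁴-read fixtures for
P ∈ {1, 2, 4, 8}, with and without an adjacency graph; partition quality
against exhaustive enumeration for ≤ 8 items and P ≤ 4 plus 10³ random
graphs for component atomicity. The full suite completes in roughly a
minute and a half. All randomness flows through explicit integer seeds
(numpy `default_rng` and the filters' hash seed); reruns are bit-identical,
and the serial and process-pool pipeline paths produce byte-identical SAM
(modulo the `@PG` line).
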