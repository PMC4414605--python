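"""Route reads to partitions through per-partition Bloom filters.

Every b-mer (b = minimum aligner seed length, 20 here) of each read is
queried against each partition's filter; a read goes to every partition
with at least one hit. Because the filter has no false negatives, a read
always reaches the partition holding its source contig; false-positive
hits send some reads to extra partitions, which only adds alignment work.
"""

from dispatchmap import (
    build_filter, dispatch_all, fragment, gen_genome, plan_partitions,
    simulate_reads,
)

genome = gen_genome(100_000, seed=2)
contigs, _ = fragment(genome, 8, overlap=100, seed=2)
reads, truth = simulate_reads(contigs, 5_000, 100, error_rate=0.0, seed=2)

P = 4
plan = plan_partitions(contigs, P)
parts = [[t for t in contigs if plan.assignment[t.id] == p] for p in range(P)]
filters = [build_filter(part, b=20, r=8, seed=5) for part in parts]

table, per_part = dispatch_all(reads, filters)
n = len(reads)
reached = sum(
    plan.assignment[truth[r.id].contig] in table.destinations[r.id] for r in reads
)
print(f"{n} reads over {P} partitions: {n - table.discarded} dispatched, "
      f"{table.discarded} discarded")
print(f"reads reaching their true source partition: {reached}/{n}")
print(f"mean destinations per read: {table.multiplicity() / n:.2f} "
      f"(excess above 1.0 is false-positive workload)")
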