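"""Shared synthetic fixtures.

Everything is generated in-process from fixed seeds; the heavy draft-assembly
fixture (100 kb genome, 8 overlapping contigs, 10,000 error-free 100 bp
reads) is session-scoped because several end-to-end suites reuse it.
"""

import pytest

from dispatchmap.align import build_seed_index, exact_map
from dispatchmap.synthetic import fragment, gen_genome, simulate_reads


class Assembly:
    def __init__(self, contigs, graph, reads, truth):
        self.contigs = contigs
        self.graph = graph
        self.reads = reads
        self.truth = truth
        self.tseqs = {t.id: t.seq for t in contigs}


@pytest.fixture(scope="session")
def assembly():
    """Draft-assembly fixture: 100 kb genome, 8 contigs sharing 100 bp
    overlaps, 10k error-free reads of length 100."""
    genome = gen_genome(100_000, seed=11)
    contigs, graph = fragment(genome, 8, overlap=100, seed=11)
    reads, truth = simulate_reads(contigs, 10_000, 100, error_rate=0.0, seed=11)
    return Assembly(contigs, graph, reads, truth)


@pytest.fixture(scope="session")
def direct_alignment(assembly):
    """Oracle: every fixture read aligned against the unpartitioned targets."""
    idx = build_seed_index(assembly.contigs, l=20)
    return {r.id: exact_map(r, idx, assembly.tseqs) for r in assembly.reads}


@pytest.fixture(scope="session")
def static_assembly():
    """Static unrelated-target fixture: the same genome cut into 8
    non-overlapping contigs (no adjacency), 10k error-free reads."""
    genome = gen_genome(100_000, seed=11)
    contigs, graph = fragment(genome, 8, overlap=0, seed=11, keep_edge_fraction=0.0)
    reads, truth = simulate_reads(contigs, 10_000, 100, error_rate=0.0, seed=12)
    return Assembly(contigs, graph, reads, truth)


@pytest.fixture(scope="session")
def pipeline_runner():
    """In-memory partition -> index -> dispatch -> align -> merge; returns
    (plan, dispatch table, merged best-mode records keyed by read ID)."""
    from dispatchmap.bloom import build_filter
    from dispatchmap.dispatch import dispatch_all
    from dispatchmap.align import align_partition
    from dispatchmap.merge import MergePolicy, merge_best
    from dispatchmap.partition import plan_partitions

    def run(asm, P, graph=None, b=20, l=20, seed=7):
        plan = plan_partitions(asm.contigs, P, graph)
        parts = [
            [t for t in asm.contigs if plan.assignment[t.id] == p] for p in range(P)
        ]
        filters = [build_filter(part, b=b, r=8, seed=seed) for part in parts]
        table, per_part = dispatch_all(asm.reads, filters)
        streams = [
            align_partition(parts[p], per_part[p], l=l)[1] if parts[p] else []
            for p in range(P)
        ]
        merged = merge_best(
            streams, table.discarded_ids(), MergePolicy(),
            expected_ids=[r.id for r in asm.reads],
        )
        return plan, table, {r.qname: r for r in merged}

    return run


def aln_fields(rec):
    """(rname, pos, strand, mapq, match length) comparison key; unmapped
    records collapse to a single sentinel."""
    if not rec.is_mapped:
        return ("*", 0, "+", 0, 0)
    return (rec.rname, rec.pos, rec.strand, rec.mapq, rec.tags.get("AS", 0))


@pytest.fixture(scope="session")
def small_assembly():
    """Lighter multi-component fixture for pipeline-level tests: four
    independent 20 kb chromosomes, each fragmented into 3 overlapping
    graph-linked contigs, 2,000 reads with 0.5% substitution errors."""
    contigs, edges, nodes = [], set(), set()
    for chrom in range(4):
        g = gen_genome(20_000, seed=100 + chrom)
        cs, gr = fragment(g, 3, overlap=100, seed=100 + chrom)
        cs = [type(c)(f"chr{chrom}_{c.id}", c.seq) for c in cs]
        contigs.extend(cs)
        nodes.update(c.id for c in cs)
        for i in range(len(cs) - 1):
            edges.add(frozenset((cs[i].id, cs[i + 1].id)))
    from dispatchmap.partition import AdjacencyGraph

    graph = AdjacencyGraph(nodes=nodes, edges=edges)
    reads, truth = simulate_reads(contigs, 2_000, 100, error_rate=0.005, seed=42)
    return Assembly(contigs, graph, reads, truth)
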