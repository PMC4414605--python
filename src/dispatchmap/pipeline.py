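"""End-to-end pipeline: distribute -> index -> dispatch -> align -> merge.

Each per-partition stage is a pure function of its partition's files, so
partitions can be processed serially or by a process pool with identical
results; stage outputs are persisted so any stage can be rerun alone.
"""

from __future__ import annotations

import json
import os
from collections import Counter
from concurrent.futures import ProcessPoolExecutor
from typing import Optional

from dispatchmap import align as _align
from dispatchmap import bloom as _bloom
from dispatchmap.dispatch import choose_b, dispatch_all
from dispatchmap.io_formats import read_fasta, read_fastq, read_sam, write_sam
from dispatchmap.merge import MergePolicy, merge_best, merge_headers, merge_multi
from dispatchmap.partition import (
    AdjacencyGraph,
    plan_partitions,
    read_manifest,
    write_partition_fastas,
)


def index_partition_file(part_fasta: str, b: int, r: float, seed: int, out_bf: str) -> dict:
    """Build and save one partition's Bloom filter; returns summary stats."""
    targets = list(read_fasta(part_fasta))
    f = _bloom.build_filter(targets, b=b, r=r, seed=seed) if targets else None
    if f is None:
        f = _bloom.BloomFilter(m=1, k=1, b=b, seed=seed)
    f.save(out_bf)
    return {"n_inserted": f.n_inserted, "m": f.m, "k": f.k,
            "occupancy": f.occupancy() if f.m > 1 else 0.0}


def align_partition_file(
    part_fasta: str, part_reads: str, out_sam: str, l: int, aligner: str = "builtin"
) -> int:
    """Align one partition's dispatched reads and persist the SAM; returns the
    record count. Pure function of its inputs (safe to run in a worker)."""
    targets = list(read_fasta(part_fasta))
    reads = list(read_fastq(part_reads)) if os.path.exists(part_reads) else []
    if aligner == "builtin":
        header, records = _align.align_partition(targets, reads, l=l)
    else:
        commands = _align.ADAPTER_PRESETS.get(aligner, [aligner])
        header, records = _align.external_adapter(
            commands, part_fasta, part_reads, name=aligner
        )
    write_sam(out_sam, header, records)
    return len(records)


def run_pipeline(
    targets_path: str,
    reads_path: str,
    outdir: str,
    P: int = 2,
    graph_path: Optional[str] = None,
    min_seed: int = _align.DEFAULT_MIN_SEED,
    b: Optional[int] = None,
    r: float = 8.0,
    seed: int = 0,
    aligner: str = "builtin",
    mode: str = "best",
    max_records: int = 1,
    emit_unmapped: bool = True,
    threads: int = 1,
) -> dict:
    """Run the full workflow and write ``merged.sam`` plus ``report.json``
    under ``outdir``; returns the run report."""
    os.makedirs(outdir, exist_ok=True)
    b = choose_b(min_seed, b)

    # distribute
    targets = list(read_fasta(targets_path))
    graph = AdjacencyGraph.from_tsv(graph_path) if graph_path else None
    plan = plan_partitions(targets, P, graph)
    part_fastas = write_partition_fastas(targets, plan, outdir)

    # index (per-partition Bloom filters)
    filter_stats = []
    for p, fa in enumerate(part_fastas):
        stats = index_partition_file(fa, b, r, seed, os.path.join(outdir, f"part_{p}.bf"))
        filter_stats.append(stats)
    filters = [
        _bloom.BloomFilter.load(os.path.join(outdir, f"part_{p}.bf"))
        for p in range(P)
    ]

    # dispatch
    reads = list(read_fastq(reads_path))
    table, _ = dispatch_all(reads, filters, outdir)

    # align (per partition; pure per-partition stage, pool-safe)
    jobs = [
        (part_fastas[p], os.path.join(outdir, f"part_{p}.reads.fq"),
         os.path.join(outdir, f"part_{p}.sam"), min_seed, aligner)
        for p in range(P)
    ]
    if threads > 1:
        with ProcessPoolExecutor(max_workers=threads) as pool:
            list(pool.map(_align_job, jobs))
    else:
        for job in jobs:
            _align_job(job)

    # merge
    final_path = os.path.join(outdir, "merged.sam")
    merge_files(
        [os.path.join(outdir, f"part_{p}.sam") for p in range(P)],
        os.path.join(outdir, "partitions.tsv"),
        final_path,
        discarded_ids=table.discarded_ids(),
        policy=MergePolicy(mode=mode, max_records=max_records,
                           emit_unmapped=emit_unmapped),
        expected_ids=[rd.id for rd in reads],
    )

    multiplicity = Counter(len(d) for d in table.destinations.values())
    report = {
        "P": P, "b": b, "min_seed": min_seed, "r": r, "seed": seed,
        "n_targets": len(targets),
        "partition_loads": plan.loads,
        "filters": filter_stats,
        "n_reads": len(reads),
        "dispatched": len(reads) - table.discarded,
        "discarded": table.discarded,
        "dispatch_multiplicity": {str(k): v for k, v in sorted(multiplicity.items())},
        "final_sam": final_path,
    }
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _align_job(job: tuple) -> int:
    part_fasta, part_reads, out_sam, l, aligner = job
    return align_partition_file(part_fasta, part_reads, out_sam, l, aligner)


def merge_files(
    sam_paths: list[str],
    manifest_path: str,
    out_sam: str,
    discarded_ids: list[str] = (),
    policy: Optional[MergePolicy] = None,
    expected_ids: Optional[list[str]] = None,
) -> None:
    """Standalone merge stage over persisted partition SAMs."""
    policy = policy or MergePolicy()
    headers, streams = [], []
    for path in sam_paths:
        h, recs = read_sam(path)
        headers.append(h)
        streams.append(recs)
    _, manifest_rows = read_manifest(manifest_path)
    header = merge_headers(headers, manifest_rows)
    if policy.mode == "best":
        records = merge_best(streams, discarded_ids, policy, expected_ids)
    else:
        records = merge_multi(streams, discarded_ids, policy, expected_ids)
    write_sam(out_sam, header, records)
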