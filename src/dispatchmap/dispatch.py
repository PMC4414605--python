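"""Bloom-filter read dispatch.

Every b-mer of a read is queried against every partition's filter; the read
is routed to each partition with at least one hit and discarded if none hit.
Because the filters have no false negatives and b is at most the minimum
seed length l of the aligner, any read with an exact match of length >= b to
either strand of a partition's targets is guaranteed to reach that
partition; false-positive hits only add alignment workload and are removed
by the merge stage.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from dispatchmap.bloom import BloomFilter, base_hashes, canonical
from dispatchmap.io_formats import ReadRec, write_fastq


def choose_b(l: int, b: Optional[int] = None) -> int:
    """Default b-mer length: b = l, the largest value that cannot miss any
    seed-length exact match. An explicit override must satisfy b <= l."""
    if l < 1:
        raise ValueError(f"minimum seed length l must be >= 1, got {l}")
    if b is None:
        return l
    if b < 1 or b > l:
        raise ValueError(f"b must satisfy 1 <= b <= l={l}, got {b}")
    return b


@dataclass
class DispatchTable:
    """Per-read destination partitions; an empty set means discarded."""

    destinations: dict[str, tuple[int, ...]] = field(default_factory=dict)

    @property
    def discarded(self) -> int:
        return sum(1 for d in self.destinations.values() if not d)

    def discarded_ids(self) -> list[str]:
        return [r for r, d in self.destinations.items() if not d]

    def multiplicity(self) -> int:
        """Total dispatch events (reads routed to multiple partitions count
        once per destination)."""
        return sum(len(d) for d in self.destinations.values())

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="ascii") as fh:
            fh.write("read_id\tpartitions\n")
            for r, d in self.destinations.items():
                fh.write(f"{r}\t{','.join(map(str, d)) if d else '-'}\n")


def _check_filters(filters: Sequence[BloomFilter]) -> int:
    if not filters:
        raise ValueError("at least one filter is required")
    bs = {f.b for f in filters}
    if len(bs) != 1:
        raise ValueError(f"filters disagree on b-mer length: {sorted(bs)}")
    seeds = {f.seed for f in filters}
    if len(seeds) != 1:
        raise ValueError(f"filters disagree on hash seed: {sorted(seeds)}")
    return bs.pop()


def dispatch_read(read: ReadRec, filters: Sequence[BloomFilter]) -> set[int]:
    """Partitions whose filter hits at least one canonical b-mer of the read.

    All b-mer positions are scanned with stride 1 (N-containing b-mers
    skipped); each partition stops being queried after its first hit. A read
    shorter than b has no b-mers and gets an empty set.
    """
    b = _check_filters(filters)
    seed = filters[0].seed
    pending = set(range(len(filters)))
    hits: set[int] = set()
    seq = read.seq
    for i in range(len(seq) - b + 1):
        c = canonical(seq[i : i + b])
        if c is None:
            continue
        g1, g2 = base_hashes(c.encode("ascii"), seed)
        for p in tuple(pending):
            if filters[p].contains_hashed(g1, g2):
                hits.add(p)
                pending.discard(p)
        if not pending:
            break
    return hits


def dispatch_all(
    reads: Iterable[ReadRec],
    filters: Sequence[BloomFilter],
    outdir: Optional[str | os.PathLike] = None,
) -> tuple[DispatchTable, list[list[ReadRec]]]:
    """Dispatch every read; optionally persist per-partition FASTQ files
    (part_<p>.reads.fq), dispatch.tsv and discarded.txt under ``outdir``.

    Reads routed to several partitions are duplicated into each partition's
    file so partitions remain independently alignable. Returns the table and
    the per-partition read lists (input order preserved).
    """
    _check_filters(filters)
    table = DispatchTable()
    per_part: list[list[ReadRec]] = [[] for _ in filters]
    for read in reads:
        dest = dispatch_read(read, filters)
        table.destinations[read.id] = tuple(sorted(dest))
        for p in dest:
            per_part[p].append(read)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        for p, part_reads in enumerate(per_part):
            write_fastq(part_reads, os.path.join(outdir, f"part_{p}.reads.fq"))
        with open(os.path.join(outdir, "discarded.txt"), "w") as fh:
            for rid in table.discarded_ids():
                fh.write(rid + "\n")
        table.to_tsv(os.path.join(outdir, "dispatch.tsv"))
    return table, per_part
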