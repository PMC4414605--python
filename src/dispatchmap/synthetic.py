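"""Ground-truthed synthetic fixtures: random genomes, fragmented contig sets
with overlap-derived adjacency graphs, and simulated reads with known source
coordinates.

The generator emulates the draft-assembly use case: a genome is tiled into
overlapping contigs (consecutive contigs share ``overlap`` bases and are
linked by an adjacency edge, as an assembler would report); reads are drawn
uniformly over valid (contig, offset) start positions on a random strand
with independent per-base substitution errors. Every read's true source is
recorded, so dispatch recall and alignment accuracy can be scored without
any external reference.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from dispatchmap.bloom import reverse_complement
from dispatchmap.io_formats import ReadRec, TargetSeq
from dispatchmap.partition import AdjacencyGraph

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Defaults model a small draft assembly: a 100 kb genome split into 8
    overlapping contigs, 10,000 error-free 100 bp reads."""

    genome_length: int = 100_000
    n_contigs: int = 8
    overlap: int = 100
    n_reads: int = 10_000
    read_length: int = 100
    error_rate: float = 0.0
    keep_edge_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.genome_length, self.n_contigs, self.n_reads, self.read_length) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 <= self.error_rate < 1:
            raise ValueError(f"error_rate must be in [0,1), got {self.error_rate}")
        if self.overlap < 0:
            raise ValueError("overlap must be >= 0")


@dataclass(frozen=True)
class ReadTruth:
    """True origin of one simulated read."""

    contig: str
    offset: int  # 0-based on the contig's forward strand
    strand: str  # '+' or '-'
    n_errors: int


def gen_genome(length: int, seed: int = 0) -> str:
    """I.i.d. uniform A/C/G/T sequence, reproducible from the seed."""
    if length < 1:
        raise ValueError(f"genome length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def fragment(
    genome: str,
    n_contigs: int,
    overlap: int = 0,
    seed: int = 0,
    keep_edge_fraction: float = 1.0,
) -> tuple[list[TargetSeq], AdjacencyGraph]:
    """Tile the genome into ``n_contigs`` contigs at random breakpoints;
    consecutive contigs share ``overlap`` bases and get an adjacency edge.

    A fraction (1 - keep_edge_fraction) of edges is withheld, splitting the
    graph into several components; keep_edge_fraction=0 with overlap=0 gives
    the unrelated-target (static reference) scenario. Concatenating the
    contigs minus the overlaps reconstructs the genome exactly.
    """
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    min_core = overlap + 1
    slack = len(genome) - n_contigs * min_core
    if slack < 0:
        raise ValueError(
            f"cannot cut a {len(genome)} bp genome into {n_contigs} contigs "
            f"with overlap {overlap}"
        )
    rng = np.random.default_rng(seed)
    # core segment boundaries: sorted random offsets plus the minimum spacing
    raw = np.sort(rng.integers(0, slack + 1, size=n_contigs - 1))
    cuts = [int(raw[i]) + (i + 1) * min_core for i in range(n_contigs - 1)]
    starts = [0] + cuts
    ends = cuts + [len(genome)]
    width = len(str(n_contigs))
    contigs = [
        TargetSeq(
            f"contig{str(i + 1).zfill(width)}",
            genome[starts[i] : min(ends[i] + overlap, len(genome))],
        )
        for i in range(n_contigs)
    ]
    nodes = {c.id for c in contigs}
    all_edges = [
        frozenset((contigs[i].id, contigs[i + 1].id)) for i in range(n_contigs - 1)
    ]
    kept = [e for e in all_edges if rng.random() < keep_edge_fraction]
    return contigs, AdjacencyGraph(nodes=nodes, edges=set(kept))


def simulate_reads(
    targets: Sequence[TargetSeq],
    n_reads: int,
    read_length: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[ReadRec], dict[str, ReadTruth]]:
    """Draw reads uniformly over all valid (contig, start) positions, strand
    Bernoulli(0.5), independent substitution errors at ``error_rate``.

    Returns the reads (constant quality 'I') and a read-ID -> ReadTruth map.
    """
    eligible = [t for t in targets if t.length >= read_length]
    if not eligible:
        raise ValueError(f"no target is at least {read_length} bp long")
    rng = np.random.default_rng(seed)
    n_starts = np.array([t.length - read_length + 1 for t in eligible], dtype=float)
    probs = n_starts / n_starts.sum()
    contig_idx = rng.choice(len(eligible), size=n_reads, p=probs)
    strands = rng.random(n_reads) < 0.5
    reads: list[ReadRec] = []
    truth: dict[str, ReadTruth] = {}
    width = len(str(n_reads))
    for j in range(n_reads):
        t = eligible[contig_idx[j]]
        off = int(rng.integers(0, t.length - read_length + 1))
        frag = t.seq[off : off + read_length]
        strand = "-" if strands[j] else "+"
        if strand == "-":
            frag = reverse_complement(frag)
        n_err = 0
        if error_rate > 0:
            err_mask = rng.random(read_length) < error_rate
            if err_mask.any():
                arr = bytearray(frag, "ascii")
                for pos in np.flatnonzero(err_mask):
                    old = arr[pos]
                    choices = [b for b in b"ACGT" if b != old]
                    arr[pos] = choices[int(rng.integers(0, 3))]
                    n_err += 1
                frag = arr.decode("ascii")
        rid = f"read{str(j + 1).zfill(width)}"
        reads.append(ReadRec(rid, frag, "I" * read_length))
        truth[rid] = ReadTruth(t.id, off, strand, n_err)
    return reads, truth


def write_truth(truth: dict[str, ReadTruth], path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["read_id", "contig", "offset", "strand", "n_errors"])
        for rid, t in truth.items():
            w.writerow([rid, t.contig, t.offset, t.strand, t.n_errors])


def read_truth(path: str | os.PathLike) -> dict[str, ReadTruth]:
    truth: dict[str, ReadTruth] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            truth[row["read_id"]] = ReadTruth(
                row["contig"], int(row["offset"]), row["strand"], int(row["n_errors"])
            )
    return truth
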