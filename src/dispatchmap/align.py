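"""Per-partition alignment: a built-in seed-and-extend exact mapper plus an
adapter contract for external aligners.

The built-in mapper indexes every l-mer of the partition's targets
(canonical key, strand recorded), seeds each read l-mer, extends every hit
to the maximal exact match containing it, and reports the longest exact
match as a soft-clipped single-M SAM record. It performs exact matching
only — no mismatches or gaps inside the reported run — which is enough to
exercise the dispatch/merge machinery end-to-end without external binaries.
Real production use plugs in an external aligner through the adapter
templates.
"""

from __future__ import annotations

import os
import shlex
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from dispatchmap.bloom import canonical, reverse_complement
from dispatchmap.io_formats import (
    AlnRecord,
    FLAG_REVERSE,
    ReadRec,
    SamHeader,
    TargetSeq,
    read_sam,
)

DEFAULT_MIN_SEED = 20  # exposed as --min-seed; also the default b via choose_b

MAPQ_UNIQUE = 60
MAPQ_REPEAT = 0


@dataclass
class SeedIndex:
    """Hash index: canonical l-mer -> occurrences (target, 0-based offset, strand)."""

    l: int
    table: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    target_order: dict[str, int] = field(default_factory=dict)


def build_seed_index(targets: Sequence[TargetSeq], l: int) -> SeedIndex:
    """Index every l-mer occurrence of every target. Hit lists are ordered by
    target input order, then offset."""
    if l < 1:
        raise ValueError(f"seed length l must be >= 1, got {l}")
    idx = SeedIndex(l=l)
    for order, t in enumerate(targets):
        idx.target_order[t.id] = order
        seq = t.seq
        for off in range(len(seq) - l + 1):
            kmer = seq[off : off + l]
            key = canonical(kmer)
            if key is None:
                continue
            strand = "+" if kmer == key else "-"
            idx.table.setdefault(key, []).append((t.id, off, strand))
    return idx


@dataclass(frozen=True)
class _Match:
    length: int
    read_start: int  # in original read coordinates
    t_order: int
    tid: str
    t_start: int  # 0-based
    strand: str
    clip_left: int  # in reported-SEQ coordinates
    clip_right: int

    @property
    def rank(self) -> tuple:
        return (
            -self.length, self.read_start, self.t_order, self.t_start,
            0 if self.strand == "+" else 1,
        )


def _extend(query: str, target: str, qi: int, ti: int, l: int) -> tuple[int, int]:
    """Maximal exact run around the seed query[qi:qi+l] == target[ti:ti+l];
    returns (query_start, query_end) of the run. N never matches."""
    left = 0
    while qi - left - 1 >= 0 and ti - left - 1 >= 0:
        a, b = query[qi - left - 1], target[ti - left - 1]
        if a != b or a == "N":
            break
        left += 1
    right = 0
    while qi + l + right < len(query) and ti + l + right < len(target):
        a, b = query[qi + l + right], target[ti + l + right]
        if a != b or a == "N":
            break
        right += 1
    return qi - left, qi + l + right


def exact_map(
    read: ReadRec,
    idx: SeedIndex,
    targets: dict[str, str],
) -> AlnRecord:
    """Map one read by seed-and-extend exact matching.

    The longest exact match (either strand) wins; ties break by leftmost
    read offset, then target input order, then smaller target position, then
    forward strand. MAPQ is 60 when the maximal length is achieved at exactly
    one (target, position, strand), else 0. Reverse-strand hits carry flag
    0x10 with reverse-complemented SEQ. No match of length >= l -> unmapped.
    """
    l = idx.l
    seq = read.seq
    n = len(seq)
    qual = read.qual if read.qual is not None else "I" * n
    rc_seq: Optional[str] = None
    matches: list[_Match] = []
    # one extension per (tid, strand, diagonal) unless a later seed on the
    # same diagonal falls outside every interval already extended there
    extended: dict[tuple[str, str, int], list[tuple[int, int]]] = {}

    for i in range(n - l + 1):
        kmer = seq[i : i + l]
        key = canonical(kmer)
        if key is None:
            continue
        hits = idx.table.get(key)
        if not hits:
            continue
        kmer_is_canon = kmer == key
        kmer_palindrome = kmer == reverse_complement(kmer)
        for tid, off, tstrand in hits:
            tseq = targets[tid]
            forward = (tstrand == "+") == kmer_is_canon
            orientations = []
            if forward or kmer_palindrome:
                orientations.append("+")
            if (not forward) or kmer_palindrome:
                orientations.append("-")
            for strand in orientations:
                if strand == "+":
                    qi = i
                    query = seq
                else:
                    if rc_seq is None:
                        rc_seq = reverse_complement(seq)
                    qi = n - l - i
                    query = rc_seq
                diag_key = (tid, strand, off - qi)
                spans = extended.setdefault(diag_key, [])
                if any(s <= qi < e for s, e in spans):
                    continue
                qs, qe = _extend(query, tseq, qi, off, l)
                spans.append((qs, qe))
                length = qe - qs
                t_start = off - (qi - qs)
                read_start = qs if strand == "+" else n - qe
                matches.append(
                    _Match(
                        length=length, read_start=read_start,
                        t_order=idx.target_order[tid], tid=tid, t_start=t_start,
                        strand=strand, clip_left=qs, clip_right=len(query) - qe,
                    )
                )

    if not matches:
        return AlnRecord.unmapped(read.id, seq, qual)

    best_len = max(m.length for m in matches)
    top = [m for m in matches if m.length == best_len]
    loci = {(m.tid, m.t_start, m.strand) for m in top}
    best = min(top, key=lambda m: m.rank)
    mapq = MAPQ_UNIQUE if len(loci) == 1 else MAPQ_REPEAT

    if best.strand == "+":
        out_seq, out_qual, flag = seq, qual, 0
    else:
        out_seq = rc_seq if rc_seq is not None else reverse_complement(seq)
        out_qual = qual[::-1]
        flag = FLAG_REVERSE
    cigar = ""
    if best.clip_left:
        cigar += f"{best.clip_left}S"
    cigar += f"{best.length}M"
    if best.clip_right:
        cigar += f"{best.clip_right}S"
    return AlnRecord(
        qname=read.id, flag=flag, rname=best.tid, pos=best.t_start + 1,
        mapq=mapq, cigar=cigar, seq=out_seq, qual=out_qual,
        tags={"AS": best.length, "NM": 0},
    )


def make_header(targets: Sequence[TargetSeq], extra_pg: str = "") -> SamHeader:
    pg = "ID:dispatchmap\tPN:dispatchmap"
    if extra_pg:
        pg += f"\t{extra_pg}"
    return SamHeader(sq=[(t.id, t.length) for t in targets], pg=[pg])


def align_partition(
    targets: Sequence[TargetSeq],
    reads: Iterable[ReadRec],
    l: int = DEFAULT_MIN_SEED,
) -> tuple[SamHeader, list[AlnRecord]]:
    """Align reads against one partition's targets with the built-in mapper:
    one record per read, header @SQ in target input order."""
    idx = build_seed_index(targets, l)
    tseqs = {t.id: t.seq for t in targets}
    records = [exact_map(read, idx, tseqs) for read in reads]
    return make_header(targets), records


# ---------------------------------------------------------------------------
# external aligner adapters

ADAPTER_PRESETS: dict[str, list[str]] = {
    "bwa": ["bwa index {target}", "bwa mem {target} {reads}"],
    "bowtie2": ["bowtie2-build {target} {target}", "bowtie2 -x {target} -U {reads}"],
    "novoalign": ["novoindex {target}.ndx {target}", "novoalign -d {target}.ndx -f {reads} -o SAM"],
}


class AdapterError(RuntimeError):
    pass


def render_adapter_argv(template: str, part_fasta: str, part_reads: str) -> list[str]:
    """Split the template first, then substitute placeholders token-wise, so
    paths containing spaces stay single argv entries."""
    return [
        tok.format(target=part_fasta, reads=part_reads)
        for tok in shlex.split(template)
    ]


def external_adapter(
    commands: Sequence[str] | str,
    part_fasta: str | os.PathLike,
    part_reads: str | os.PathLike,
    name: str = "external",
) -> tuple[SamHeader, list[AlnRecord]]:
    """Run an index-then-align command sequence; the last command's stdout is
    consumed as SAM. ``commands`` may be a preset name, a single template, or
    a list of templates with {target} and {reads} placeholders."""
    if isinstance(commands, str):
        commands = ADAPTER_PRESETS.get(commands, [commands])
    part_fasta, part_reads = os.fspath(part_fasta), os.fspath(part_reads)
    stdout = b""
    for template in commands:
        argv = render_adapter_argv(template, part_fasta, part_reads)
        if shutil.which(argv[0]) is None:
            raise AdapterError(
                f"adapter {name!r}: executable {argv[0]!r} not found on PATH"
            )
        proc = subprocess.run(argv, capture_output=True)
        if proc.returncode != 0:
            raise AdapterError(
                f"adapter {name!r}: {argv[0]} exited with code {proc.returncode}: "
                f"{proc.stderr.decode(errors='replace').strip()}"
            )
        stdout = proc.stdout
    with tempfile.NamedTemporaryFile("wb", suffix=".sam", delete=False) as tmp:
        tmp.write(stdout)
        tmp_path = tmp.name
    try:
        return read_sam(tmp_path)
    finally:
        os.unlink(tmp_path)
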