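"""Streaming I/O: FASTA/FASTQ (plain or gzip), strict minimal SAM, manifest TSV.

Coordinates are 0-based half-open everywhere inside the package; conversion
to SAM's 1-based convention happens only when a record is serialized.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Optional

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator


class ParseError(ValueError):
    """Malformed input; message carries file context."""


class SamValidationError(ValueError):
    """A SAM record violates the strict-mode contract."""


# ---------------------------------------------------------------------------
# sequence records


@dataclass(frozen=True)
class TargetSeq:
    """One named target sequence (contig or chromosome)."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadRec:
    """One query read; ``qual`` is None for FASTA input."""

    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ParseError(
                f"read {self.id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )


def _open_text(path: str | os.PathLike) -> IO[str]:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "r", encoding="ascii", newline=None)


def read_fasta(path: str | os.PathLike) -> Iterator[TargetSeq]:
    """Iterate FASTA records in file order; sequences are uppercased.

    Multi-line records, CRLF line endings and gzip compression are accepted.
    """
    with _open_text(path) as fh:
        n = 0
        try:
            for title, seq in SimpleFastaParser(fh):
                n += 1
                name = title.split()[0] if title.split() else ""
                if not name:
                    raise ParseError(f"{path}: record {n}: empty FASTA header")
                if not seq:
                    raise ParseError(f"{path}: record {n} ({name!r}): empty sequence")
                yield TargetSeq(name, seq.upper())
        except ValueError as exc:
            if isinstance(exc, ParseError):
                raise
            raise ParseError(f"{path}: record {n + 1}: {exc}") from exc


def write_fasta(records: Iterable[TargetSeq], path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w", encoding="ascii") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path: str | os.PathLike, fasta_quality: str = "I") -> Iterator[ReadRec]:
    """Iterate reads from FASTQ, or from FASTA with a synthesized constant
    quality character (``fasta_quality``)."""
    with _open_text(path) as fh:
        head = fh.read(1)
        fh.seek(0)
        n = 0
        try:
            if head == ">":
                for title, seq in SimpleFastaParser(fh):
                    n += 1
                    name = title.split()[0]
                    yield ReadRec(name, seq.upper(), fasta_quality * len(seq))
            else:
                for title, seq, qual in FastqGeneralIterator(fh):
                    n += 1
                    name = title.split()[0]
                    if len(qual) != len(seq):
                        raise ParseError(
                            f"{path}: record {n} ({name!r}): quality/sequence length mismatch"
                        )
                    yield ReadRec(name, seq.upper(), qual)
        except ValueError as exc:
            if isinstance(exc, ParseError):
                raise
            raise ParseError(f"{path}: record {n + 1}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRec], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="ascii") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# SAM


@dataclass
class SamHeader:
    """Ordered @SQ lines plus @PG program lines."""

    sq: list[tuple[str, int]] = field(default_factory=list)
    pg: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r for r, _ in self.sq]
        if len(names) != len(set(names)):
            raise SamValidationError("duplicate reference name in @SQ lines")
        for rname, ln in self.sq:
            if ln < 1:
                raise SamValidationError(f"@SQ {rname}: LN must be >= 1, got {ln}")

    def lengths(self) -> dict[str, int]:
        return dict(self.sq)

    def to_lines(self) -> list[str]:
        lines = ["@HD\tVN:1.6\tSO:unsorted"]
        lines += [f"@SQ\tSN:{r}\tLN:{ln}" for r, ln in self.sq]
        lines += [f"@PG\t{p}" for p in self.pg]
        return lines


FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_SECONDARY = 0x100

_CIGAR_READ_OPS = set("MIS=X")
_CIGAR_REF_OPS = set("MDN=X")


def _cigar_ops(cigar: str) -> list[tuple[int, str]]:
    ops, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if not num or ch not in "MIDNSHP=X":
                raise SamValidationError(f"malformed CIGAR {cigar!r}")
            ops.append((int(num), ch))
            num = ""
    if num:
        raise SamValidationError(f"malformed CIGAR {cigar!r}")
    return ops


def cigar_read_len(cigar: str) -> int:
    return sum(n for n, op in _cigar_ops(cigar) if op in _CIGAR_READ_OPS)


def cigar_ref_len(cigar: str) -> int:
    return sum(n for n, op in _cigar_ops(cigar) if op in _CIGAR_REF_OPS)


@dataclass
class AlnRecord:
    """One SAM-semantics alignment record (pos is 1-based, 0 if unmapped)."""

    qname: str
    flag: int = FLAG_UNMAPPED
    rname: str = "*"
    pos: int = 0
    mapq: int = 0
    cigar: str = "*"
    seq: str = "*"
    qual: str = "*"
    tags: dict[str, int | float | str] = field(default_factory=dict)

    @property
    def is_mapped(self) -> bool:
        return not self.flag & FLAG_UNMAPPED

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def strand(self) -> str:
        return "-" if self.is_reverse else "+"

    @classmethod
    def unmapped(cls, qname: str, seq: str = "*", qual: str = "*") -> "AlnRecord":
        return cls(qname=qname, flag=FLAG_UNMAPPED, seq=seq, qual=qual)

    def _tag_fields(self) -> list[str]:
        out = []
        for name in sorted(self.tags):
            val = self.tags[name]
            if isinstance(val, bool):
                raise SamValidationError(f"tag {name}: bool is not a SAM tag type")
            if isinstance(val, int):
                out.append(f"{name}:i:{val}")
            elif isinstance(val, float):
                out.append(f"{name}:f:{val:g}")
            else:
                out.append(f"{name}:Z:{val}")
        return out

    def to_line(self) -> str:
        fields = [
            self.qname, str(self.flag), self.rname, str(self.pos),
            str(self.mapq), self.cigar, "*", "0", "0", self.seq, self.qual,
        ]
        return "\t".join(fields + self._tag_fields())

    @classmethod
    def from_line(cls, line: str) -> "AlnRecord":
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 11:
            raise ParseError(f"SAM record has {len(parts)} fields, expected >= 11")
        tags: dict[str, int | float | str] = {}
        for raw in parts[11:]:
            try:
                name, typ, val = raw.split(":", 2)
            except ValueError as exc:
                raise ParseError(f"malformed SAM tag {raw!r}") from exc
            if typ == "i":
                tags[name] = int(val)
            elif typ == "f":
                tags[name] = float(val)
            else:
                tags[name] = val
        return cls(
            qname=parts[0], flag=int(parts[1]), rname=parts[2], pos=int(parts[3]),
            mapq=int(parts[4]), cigar=parts[5], seq=parts[9], qual=parts[10],
            tags=tags,
        )

    def validate(self, header: SamHeader) -> None:
        """Strict-mode checks used by tests and the merge stage."""
        if not self.is_mapped:
            if self.rname != "*" or self.pos != 0 or self.cigar != "*":
                raise SamValidationError(
                    f"{self.qname}: unmapped record must have rname='*', pos=0, cigar='*'"
                )
            return
        lengths = header.lengths()
        if self.rname not in lengths:
            raise SamValidationError(f"{self.qname}: rname {self.rname!r} absent from header")
        if self.pos < 1:
            raise SamValidationError(f"{self.qname}: mapped record with pos {self.pos}")
        if self.seq != "*" and cigar_read_len(self.cigar) != len(self.seq):
            raise SamValidationError(
                f"{self.qname}: CIGAR read length {cigar_read_len(self.cigar)} "
                f"!= |SEQ| {len(self.seq)}"
            )
        end = self.pos + cigar_ref_len(self.cigar) - 1
        if end > lengths[self.rname]:
            raise SamValidationError(
                f"{self.qname}: alignment end {end} exceeds {self.rname} "
                f"length {lengths[self.rname]}"
            )


def read_sam(path: str | os.PathLike) -> tuple[SamHeader, list[AlnRecord]]:
    header = SamHeader()
    records: list[AlnRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    fields = dict(f.split(":", 1) for f in line.split("\t")[1:])
                    try:
                        header.sq.append((fields["SN"], int(fields["LN"])))
                    except KeyError as exc:
                        raise ParseError(f"{path}:{lineno}: @SQ missing {exc}") from exc
                elif line.startswith("@PG"):
                    header.pg.append(line.split("\t", 1)[1] if "\t" in line else "")
                continue
            try:
                records.append(AlnRecord.from_line(line))
            except (ParseError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return header, records


def write_sam(
    path: str | os.PathLike,
    header: SamHeader,
    records: Iterable[AlnRecord],
    strict: bool = False,
) -> None:
    with open(path, "w", encoding="ascii") as fh:
        for line in header.to_lines():
            fh.write(line + "\n")
        for rec in records:
            if strict:
                rec.validate(header)
            fh.write(rec.to_line() + "\n")
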