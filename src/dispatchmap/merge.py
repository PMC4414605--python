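"""Merge per-partition SAM outputs into the final alignment.

Best mode keeps, for each read, the single mapped record maximizing
(MAPQ, then alignment score AS, then a deterministic tie-break); multi mode
keeps up to N distinct records ranked the same way, flagging all but the
first as secondary. Reads discarded at dispatch (and reads unmapped in every
partition) are emitted as unmapped records so the output accounts for every
input read exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from dispatchmap.io_formats import AlnRecord, FLAG_SECONDARY, SamHeader


class MergeError(ValueError):
    pass


@dataclass
class MergePolicy:
    """mode 'best' emits exactly one record per read; 'multi' up to
    ``max_records`` distinct ones. ``flag_cross_partition_ties`` zeroes MAPQ
    when the top two candidates from different partitions tie on score,
    since per-partition MAPQs are not recalibrated across partitions."""

    mode: str = "best"
    max_records: int = 1
    emit_unmapped: bool = True
    flag_cross_partition_ties: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("best", "multi"):
            raise ValueError(f"unknown merge mode {self.mode!r}")
        if self.max_records < 1:
            raise ValueError(f"max_records must be >= 1, got {self.max_records}")


def merge_headers(
    partition_headers: Sequence[SamHeader],
    manifest_rows: Sequence[tuple[str, int]],
) -> SamHeader:
    """Combined header: @SQ for all targets in original target-file order
    (the manifest order); partitions declaring overlapping @SQ sets are a
    partitioning violation."""
    seen: dict[str, int] = {}
    for p, h in enumerate(partition_headers):
        for rname, ln in h.sq:
            if rname in seen:
                raise MergeError(
                    f"target {rname!r} declared by partitions {seen[rname]} and {p}"
                )
            seen[rname] = p
    lengths = {r: ln for h in partition_headers for r, ln in h.sq}
    missing = [r for r, _ in manifest_rows if r not in lengths]
    if missing:
        raise MergeError(f"manifest targets absent from partition headers: {missing[:5]}")
    pg = [
        "ID:dispatchmap-merge\tPN:dispatchmap\tCL:merge",
    ]
    return SamHeader(sq=[(r, lengths[r]) for r, _ in manifest_rows], pg=pg)


def _score(rec: AlnRecord) -> tuple[int, int]:
    as_tag = rec.tags.get("AS", 0)
    return (rec.mapq, as_tag if isinstance(as_tag, int) else 0)


def _rank(p: int, rec: AlnRecord) -> tuple:
    mapq, as_tag = _score(rec)
    return (-mapq, -as_tag, p, rec.rname, rec.pos, 0 if rec.strand == "+" else 1)


def _gather(
    streams: Sequence[Sequence[AlnRecord]],
    discarded_ids: Iterable[str],
    expected_ids: Optional[Iterable[str]] = None,
) -> tuple[list[str], dict[str, list[tuple[int, AlnRecord]]]]:
    """Group records by read across streams. Output read order: first
    appearance scanning streams in partition-index order, then discarded
    reads — deterministic regardless of stream arrival order (streams are
    indexed by partition)."""
    by_read: dict[str, list[tuple[int, AlnRecord]]] = {}
    order: list[str] = []
    for p, stream in enumerate(streams):
        for rec in stream:
            if rec.qname not in by_read:
                by_read[rec.qname] = []
                order.append(rec.qname)
            by_read[rec.qname].append((p, rec))
    for rid in discarded_ids:
        if rid not in by_read:
            by_read[rid] = []
            order.append(rid)
    if expected_ids is not None:
        missing = [r for r in expected_ids if r not in by_read]
        if missing:
            raise MergeError(
                f"reads in neither any stream nor discarded list: {missing[:5]}"
            )
    return order, by_read


def merge_best(
    streams: Sequence[Sequence[AlnRecord]],
    discarded_ids: Iterable[str] = (),
    policy: Optional[MergePolicy] = None,
    expected_ids: Optional[Iterable[str]] = None,
) -> list[AlnRecord]:
    """One output record per read: the best-quality mapped record across all
    partitions, or an unmapped record when none mapped (if emit_unmapped)."""
    policy = policy or MergePolicy()
    order, by_read = _gather(streams, discarded_ids, expected_ids)
    out: list[AlnRecord] = []
    for rid in order:
        mapped = [(p, r) for p, r in by_read[rid] if r.is_mapped]
        if not mapped:
            if policy.emit_unmapped:
                cands = by_read[rid]
                seq, qual = ("*", "*")
                if cands:
                    seq, qual = cands[0][1].seq, cands[0][1].qual
                out.append(AlnRecord.unmapped(rid, seq, qual))
            continue
        ranked = sorted(mapped, key=lambda pr: _rank(*pr))
        p_best, best = ranked[0]
        if (
            policy.flag_cross_partition_ties
            and len(ranked) > 1
            and _score(ranked[1][1]) == _score(best)
            and ranked[1][0] != p_best
        ):
            best = AlnRecord(**{**best.__dict__, "mapq": 0})
        out.append(best)
    return out


def merge_multi(
    streams: Sequence[Sequence[AlnRecord]],
    discarded_ids: Iterable[str] = (),
    policy: Optional[MergePolicy] = None,
    expected_ids: Optional[Iterable[str]] = None,
) -> list[AlnRecord]:
    """Up to policy.max_records distinct mapped records per read, ordered by
    the best-mode ranking; distinctness key is (rname, pos, strand, cigar);
    records after the first carry the secondary flag (0x100)."""
    policy = policy or MergePolicy(mode="multi")
    order, by_read = _gather(streams, discarded_ids, expected_ids)
    out: list[AlnRecord] = []
    for rid in order:
        mapped = sorted(
            ((p, r) for p, r in by_read[rid] if r.is_mapped),
            key=lambda pr: _rank(*pr),
        )
        emitted = 0
        seen_keys: set[tuple] = set()
        for _, rec in mapped:
            key = (rec.rname, rec.pos, rec.strand, rec.cigar)
            if key in seen_keys:
                continue
            seen_keys.add(key)
            if emitted > 0:
                rec = AlnRecord(
                    **{**rec.__dict__, "flag": rec.flag | FLAG_SECONDARY}
                )
            out.append(rec)
            emitted += 1
            if emitted >= policy.max_records:
                break
        if emitted == 0 and policy.emit_unmapped:
            cands = by_read[rid]
            seq, qual = ("*", "*")
            if cands:
                seq, qual = cands[0][1].seq, cands[0][1].qual
            out.append(AlnRecord.unmapped(rid, seq, qual))
    return out
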