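"""Projection of reference intervals onto assembly contigs via PAF alignments.

This is the liftover step of a local-pangenome workflow: given
assembly-vs-reference alignments, compute the assembly-coordinate image of a
target reference interval, decide which additional contigs deserve admission
into the pangenome under minimum-length and contig-coverage filters, and scan
contigs for translocation signatures (multi-chromosome or non-colinear block
orders, the hallmark of the serial *KIT* translocations behind
color-sidedness in cattle).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from ._util import revcomp
from .intervals import GenomicInterval
from .paf import ALIGN_OPS, PafRecord

__all__ = [
    "ProjectedSegment",
    "ContigAdmission",
    "TranslocationBlock",
    "TranslocationSignature",
    "project_interval",
    "admit_additional_contigs",
    "detect_translocation_signatures",
    "extract_region_sequences",
]


@dataclass(frozen=True)
class ProjectedSegment:
    """The image on an assembly contig of (part of) a reference interval.

    ``source`` is the aligned reference sub-interval actually covered (after
    clipping to the query interval and, with a CIGAR, to aligned bases);
    ``image`` is the corresponding contig interval, carrying the alignment
    strand. ``approximate`` marks images obtained by proportional
    interpolation because the record lacked a CIGAR.
    """

    source: GenomicInterval
    image: GenomicInterval
    identity: float
    via: PafRecord
    approximate: bool = False


def _walk_cigar(rec: PafRecord, t0: int, t1: int):
    """Span of aligned (reference, query) bases with reference pos in [t0, t1).

    Returns ``(ref_lo, ref_hi, q_lo, q_hi)`` as half-open bounds, or ``None``
    when no aligned base falls in the window (e.g. the window sits entirely
    inside a deletion).
    """
    t = rec.tstart
    q = rec.qstart if rec.strand == "+" else rec.qend
    rlo = rhi = qlo = qhi = None
    for length, op in rec.cigar:
        if op in ALIGN_OPS:
            a, b = max(t, t0), min(t + length, t1)
            if a < b:
                if rec.strand == "+":
                    s, e = q + (a - t), q + (b - t)
                else:
                    s, e = q - (b - t), q - (a - t)
                qlo = s if qlo is None else min(qlo, s)
                qhi = e if qhi is None else max(qhi, e)
                rlo = a if rlo is None else min(rlo, a)
                rhi = b if rhi is None else max(rhi, b)
            t += length
            q = q + length if rec.strand == "+" else q - length
        elif op == "I":
            q = q + length if rec.strand == "+" else q - length
        elif op in "DN":
            t += length
        # S/H/P never occur inside the PAF alignment block
    if qlo is None:
        return None
    return rlo, rhi, qlo, qhi


def _interpolate(rec: PafRecord, t0: int, t1: int):
    """CIGAR-free fallback: linear interpolation across the alignment block."""
    scale = (rec.qend - rec.qstart) / (rec.tend - rec.tstart)
    if rec.strand == "+":
        qlo = rec.qstart + round((t0 - rec.tstart) * scale)
        qhi = rec.qstart + round((t1 - rec.tstart) * scale)
    else:
        qlo = rec.qstart + round((rec.tend - t1) * scale)
        qhi = rec.qstart + round((rec.tend - t0) * scale)
    return t0, t1, qlo, qhi


def project_interval(
    records: Iterable[PafRecord], target: GenomicInterval
) -> list[ProjectedSegment]:
    """Project ``target`` through each overlapping alignment record.

    With a ``cg`` CIGAR the image is exact: the span of query bases aligned
    to reference bases inside the clipped window (a window falling entirely
    in a deletion yields no segment). Without a CIGAR the image is obtained
    by proportional interpolation and flagged ``approximate``. ``'-'`` strand
    records map reference-forward order onto query-reverse coordinates.
    """
    segments: list[ProjectedSegment] = []
    for rec in records:
        if rec.tname != target.chrom:
            continue
        t0, t1 = max(rec.tstart, target.start), min(rec.tend, target.end)
        if t0 >= t1:
            continue
        if rec.cigar is not None:
            span = _walk_cigar(rec, t0, t1)
            if span is None:
                continue
            approx = False
        else:
            span = _interpolate(rec, t0, t1)
            approx = True
        rlo, rhi, qlo, qhi = span
        identity = rec.matches / rec.block_len if rec.block_len else 0.0
        segments.append(
            ProjectedSegment(
                source=GenomicInterval(target.chrom, rlo, rhi),
                image=GenomicInterval(rec.qname, qlo, qhi, rec.strand),
                identity=identity,
                via=rec,
                approximate=approx,
            )
        )
    return segments


@dataclass(frozen=True)
class ContigAdmission:
    """Outcome of the additional-contig filters for one contig.

    A contig is admitted when its (union) aligned length reaches ``min_len``
    AND covers at least ``min_frac`` of the whole contig. Contigs failing
    only the coverage-fraction rule carry a note so that borderline cases
    are visible in reports rather than silently dropped.
    """

    contig: str
    aligned_length: int
    contig_length: int
    coverage_fraction: float
    pass_length: bool
    pass_fraction: bool
    admitted: bool
    note: str = ""


def admit_additional_contigs(
    segments: Iterable[ProjectedSegment],
    contig_lengths: Mapping[str, int],
    min_len: int = 10_000,
    min_frac: float = 0.80,
) -> list[ContigAdmission]:
    """Apply the 10 kb / 80 % admission filters per contig.

    ``aligned_length`` is the length of the union of image intervals on each
    contig (overlapping projections are not double-counted). Every decision
    is reported, passes and failures alike, sorted by contig name.
    """
    by_contig: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for seg in segments:
        if seg.image.length > 0:
            by_contig[seg.image.chrom].addi(seg.image.start, seg.image.end)
    out: list[ContigAdmission] = []
    for contig in sorted(by_contig):
        tree = by_contig[contig]
        tree.merge_overlaps(strict=False)
        aligned = sum(iv.end - iv.begin for iv in tree)
        if contig not in contig_lengths:
            raise ValueError(f"unknown length for contig {contig!r}")
        total = contig_lengths[contig]
        frac = aligned / total if total else 0.0
        pass_len = aligned >= min_len
        pass_frac = frac >= min_frac
        note = ""
        if pass_len and not pass_frac:
            note = (
                f"fails only the contig-coverage rule: "
                f"{aligned}/{total} = {frac:.1%} < {min_frac:.0%}"
            )
        out.append(
            ContigAdmission(
                contig=contig,
                aligned_length=aligned,
                contig_length=total,
                coverage_fraction=frac,
                pass_length=pass_len,
                pass_fraction=pass_frac,
                admitted=pass_len and pass_frac,
                note=note,
            )
        )
    return out


@dataclass(frozen=True)
class TranslocationBlock:
    chrom: str
    interval: GenomicInterval
    strand: str
    qstart: int
    qend: int


@dataclass
class TranslocationSignature:
    """Ordered reference blocks of one contig, in contig coordinate order."""

    contig: str
    blocks: list[TranslocationBlock]
    multi_chromosome: bool
    non_colinear: bool


def _colinear(blocks: Sequence[TranslocationBlock]) -> bool:
    """True when, per chromosome, contig order preserves reference order."""
    per_chrom: dict[str, list[TranslocationBlock]] = defaultdict(list)
    for blk in blocks:
        per_chrom[blk.chrom].append(blk)
    for chrom_blocks in per_chrom.values():
        for prev, cur in zip(chrom_blocks, chrom_blocks[1:]):
            if prev.strand != cur.strand:
                return False
            if prev.strand == "+" and cur.interval.start < prev.interval.start:
                return False
            if prev.strand == "-" and cur.interval.start > prev.interval.start:
                return False
    return True


def detect_translocation_signatures(
    records: Iterable[PafRecord],
    target: GenomicInterval,
    min_block: int = 5_000,
) -> list[TranslocationSignature]:
    """Per-contig block signatures for contigs touching the target interval.

    A contig is inspected when any of its alignments overlaps ``target``;
    all its alignments (any chromosome) then become blocks, ordered by
    contig coordinate, with blocks shorter than ``min_block`` on the contig
    suppressed as noise. Flags mark contigs aligning to more than one
    chromosome and contigs whose same-chromosome blocks are out of reference
    order (given their strands).
    """
    records = list(records)
    relevant = {
        r.qname
        for r in records
        if r.tname == target.chrom and r.tstart < target.end and r.tend > target.start
    }
    by_contig: dict[str, list[TranslocationBlock]] = defaultdict(list)
    for rec in records:
        if rec.qname not in relevant or rec.qend - rec.qstart < min_block:
            continue
        by_contig[rec.qname].append(
            TranslocationBlock(
                chrom=rec.tname,
                interval=GenomicInterval(rec.tname, rec.tstart, rec.tend, rec.strand),
                strand=rec.strand,
                qstart=rec.qstart,
                qend=rec.qend,
            )
        )
    signatures = []
    for contig in sorted(by_contig):
        blocks = sorted(by_contig[contig], key=lambda b: (b.qstart, b.qend))
        signatures.append(
            TranslocationSignature(
                contig=contig,
                blocks=blocks,
                multi_chromosome=len({b.chrom for b in blocks}) > 1,
                non_colinear=not _colinear(blocks),
            )
        )
    return signatures


def extract_region_sequences(
    source, segments: Iterable[ProjectedSegment]
) -> list[tuple[str, str]]:
    """Pull the image sequence of each segment from contig sequences.

    ``source`` may be any mapping of contig name to sliceable sequence (a
    plain dict of strings or a ``pyfaidx.Fasta``). Images on the ``'-'``
    strand are reverse-complemented. Headers encode ``contig:start-end:strand``.
    """
    out: list[tuple[str, str]] = []
    for seg in segments:
        contig = seg.image.chrom
        try:
            record = source[contig]
        except KeyError:
            raise ValueError(f"contig {contig!r} absent from sequence source") from None
        if seg.image.end > len(record):
            raise ValueError(
                f"segment {seg.image} extends past contig end ({len(record)} bp)"
            )
        seq = str(record[seg.image.start : seg.image.end])
        strand = seg.image.strand if seg.image.strand in {"+", "-"} else "+"
        if strand == "-":
            seq = revcomp(seq)
        header = f"{contig}:{seg.image.start}-{seg.image.end}:{strand}"
        out.append((header, seq))
    return out
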