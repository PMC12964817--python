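"""PAF (Pairwise mApping Format) records: parsing, validation, formatting.

A PAF line has 12 mandatory tab-separated columns followed by optional
SAM-style ``TAG:TYPE:VALUE`` tags; the ``cg:Z:`` tag carries the alignment
CIGAR. Coordinates are 0-based half-open on both query and target. For a
``'-'`` strand record the query coordinates refer to the original (forward)
query sequence while the alignment itself pairs the reverse complement of
the query with the forward target — the CIGAR walks the target forward and
the query backward from ``qend``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable

logger = logging.getLogger(__name__)

__all__ = [
    "PafRecord",
    "PafFormatError",
    "parse_paf",
    "format_paf",
    "parse_cigar",
    "cigar_query_span",
    "cigar_target_span",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

#: CIGAR operations that consume query / target bases.
QUERY_OPS = frozenset("MIS=X")
TARGET_OPS = frozenset("MDN=X")
ALIGN_OPS = frozenset("M=X")


class PafFormatError(ValueError):
    """A line that cannot be parsed as PAF at all (wrong shape, bad integer)."""


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into ``(length, op)`` pairs; reject junk."""
    ops = _CIGAR_RE.findall(cigar)
    if not ops or "".join(f"{n}{o}" for n, o in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return [(int(n), op) for n, op in ops]


def cigar_query_span(ops: Iterable[tuple[int, str]]) -> int:
    return sum(n for n, op in ops if op in QUERY_OPS)


def cigar_target_span(ops: Iterable[tuple[int, str]]) -> int:
    return sum(n for n, op in ops if op in TARGET_OPS)


@dataclass
class PafRecord:
    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    matches: int
    block_len: int
    mapq: int
    tags: dict[str, str] = field(default_factory=dict)

    @property
    def cigar(self) -> list[tuple[int, str]] | None:
        cg = self.tags.get("cg")
        return None if cg is None else parse_cigar(cg)

    def validate(self) -> None:
        """Raise ``ValueError`` on any coordinate/CIGAR inconsistency."""
        if not (0 <= self.qstart <= self.qend <= self.qlen):
            raise ValueError(
                f"query coordinates out of order for {self.qname}: "
                f"0 <= {self.qstart} <= {self.qend} <= {self.qlen} violated"
            )
        if not (0 <= self.tstart <= self.tend <= self.tlen):
            raise ValueError(
                f"target coordinates out of order for {self.qname}->{self.tname}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        ops = self.cigar
        if ops is not None:
            qspan = cigar_query_span(ops)
            tspan = cigar_target_span(ops)
            if qspan != self.qend - self.qstart:
                raise ValueError(
                    f"CIGAR query span {qspan} != qend-qstart "
                    f"{self.qend - self.qstart} for {self.qname}"
                )
            if tspan != self.tend - self.tstart:
                raise ValueError(
                    f"CIGAR target span {tspan} != tend-tstart "
                    f"{self.tend - self.tstart} for {self.qname}"
                )


_INT_FIELDS = {
    1: "qlen",
    2: "qstart",
    3: "qend",
    6: "tlen",
    7: "tstart",
    8: "tend",
    9: "matches",
    10: "block_len",
    11: "mapq",
}


def _parse_line(line: str, lineno: int) -> PafRecord:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 12:
        raise PafFormatError(
            f"PAF line {lineno}: expected >= 12 columns, got {len(cols)}"
        )
    vals: dict[str, int] = {}
    for idx, name in _INT_FIELDS.items():
        try:
            vals[name] = int(cols[idx])
        except ValueError:
            raise PafFormatError(
                f"PAF line {lineno}: field {name!r} is not an integer: {cols[idx]!r}"
            ) from None
    tags: dict[str, str] = {}
    for tag in cols[12:]:
        parts = tag.split(":", 2)
        if len(parts) != 3:
            raise PafFormatError(f"PAF line {lineno}: malformed tag {tag!r}")
        tags[parts[0]] = parts[2]
    return PafRecord(
        qname=cols[0],
        strand=cols[4],
        tname=cols[5],
        tags=tags,
        **vals,
    )


def parse_paf(stream: IO[str] | Iterable[str], invalid: list | None = None) -> list[PafRecord]:
    """Parse a PAF stream into records.

    Lines that are not PAF-shaped raise :class:`PafFormatError` naming the
    line number and field. Well-formed records that violate coordinate or
    CIGAR-consistency invariants are rejected individually: they are skipped
    and reported as ``(lineno, reason)`` in ``invalid`` when a list is
    supplied (otherwise logged as warnings).
    """
    records: list[PafRecord] = []
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        rec = _parse_line(line, lineno)
        try:
            rec.validate()
        except ValueError as exc:
            if invalid is not None:
                invalid.append((lineno, str(exc)))
            else:
                logger.warning("PAF line %d rejected: %s", lineno, exc)
            continue
        records.append(rec)
    return records


def format_paf(rec: PafRecord) -> str:
    cols = [
        rec.qname,
        str(rec.qlen),
        str(rec.qstart),
        str(rec.qend),
        rec.strand,
        rec.tname,
        str(rec.tlen),
        str(rec.tstart),
        str(rec.tend),
        str(rec.matches),
        str(rec.block_len),
        str(rec.mapq),
    ]
    for key, value in rec.tags.items():
        typ = "i" if key in {"NM", "AS"} else "Z"
        cols.append(f"{key}:{typ}:{value}")
    return "\t".join(cols)


def write_paf(records: Iterable[PafRecord], dest) -> None:
    from ._util import _as_handle

    handle, owned = _as_handle(dest)
    try:
        for rec in records:
            handle.write(format_paf(rec) + "\n")
    finally:
        if owned:
            handle.close()
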