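"""GAF (Graph Alignment Format) records and the best-alignment filter.

A GAF record stores a read's alignment to a graph as an oriented node walk
(``>n1<n2...``) with start/end in the walk's own coordinates. The
best-alignment filter reproduces a max-multimap-1 policy downstream of the
aligner: at most one record per read survives.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable

from .graph import Step

logger = logging.getLogger(__name__)

__all__ = ["GafRecord", "GafFormatError", "parse_gaf", "format_gaf", "filter_best_alignment"]

_STEP_RE = re.compile(r"([><])([^\s><]+)")


class GafFormatError(ValueError):
    pass


@dataclass
class GafRecord:
    name: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    path: tuple[Step, ...]
    path_len: int
    pstart: int
    pend: int
    matches: int
    block_len: int
    mapq: int
    tags: dict[str, str] = field(default_factory=dict)

    @property
    def path_str(self) -> str:
        return "".join(f"{'<' if rev else '>'}{nid}" for nid, rev in self.path)

    def validate(self) -> None:
        if not (0 <= self.qstart <= self.qend <= self.qlen):
            raise ValueError(f"read {self.name!r}: query coordinates out of order")
        if not (0 <= self.pstart <= self.pend <= self.path_len):
            raise ValueError(
                f"read {self.name!r}: path coordinates out of order "
                f"(0 <= {self.pstart} <= {self.pend} <= {self.path_len} violated)"
            )
        if not self.path:
            raise ValueError(f"read {self.name!r}: empty path")


def _parse_path(spec: str, name: str) -> tuple[Step, ...]:
    steps = tuple((m[1], m[0] == "<") for m in _STEP_RE.findall(spec))
    if not steps or "".join(f"{'<' if r else '>'}{n}" for n, r in steps) != spec:
        raise GafFormatError(f"read {name!r}: malformed path {spec!r}")
    return steps


def parse_gaf(stream: IO[str] | Iterable[str], invalid: list | None = None) -> list[GafRecord]:
    """Parse a GAF stream; invariant-violating records are rejected per record.

    Structurally unparseable lines raise :class:`GafFormatError` with the
    line number; records that parse but violate coordinate invariants are
    skipped and reported in ``invalid`` (or logged) with the reason.
    Whether each path node exists in the companion graph is checked later,
    at coverage-accumulation time.
    """
    records: list[GafRecord] = []
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 12:
            raise GafFormatError(
                f"GAF line {lineno}: expected >= 12 columns, got {len(cols)}"
            )
        try:
            rec = GafRecord(
                name=cols[0],
                qlen=int(cols[1]),
                qstart=int(cols[2]),
                qend=int(cols[3]),
                strand=cols[4],
                path=_parse_path(cols[5], cols[0]),
                path_len=int(cols[6]),
                pstart=int(cols[7]),
                pend=int(cols[8]),
                matches=int(cols[9]),
                block_len=int(cols[10]),
                mapq=int(cols[11]),
                tags={
                    t.split(":", 2)[0]: t.split(":", 2)[2] for t in cols[12:] if t.count(":") >= 2
                },
            )
        except ValueError as exc:
            raise GafFormatError(f"GAF line {lineno}: {exc}") from None
        try:
            rec.validate()
        except ValueError as exc:
            if invalid is not None:
                invalid.append((lineno, str(exc)))
            else:
                logger.warning("GAF line %d rejected: %s", lineno, exc)
            continue
        records.append(rec)
    return records


def format_gaf(rec: GafRecord) -> str:
    cols = [
        rec.name,
        str(rec.qlen),
        str(rec.qstart),
        str(rec.qend),
        rec.strand,
        rec.path_str,
        str(rec.path_len),
        str(rec.pstart),
        str(rec.pend),
        str(rec.matches),
        str(rec.block_len),
        str(rec.mapq),
    ]
    cols.extend(f"{k}:Z:{v}" for k, v in rec.tags.items())
    return "\t".join(cols)


def write_gaf(records: Iterable[GafRecord], dest) -> None:
    from ._util import _as_handle

    handle, owned = _as_handle(dest)
    try:
        for rec in records:
            handle.write(format_gaf(rec) + "\n")
    finally:
        if owned:
            handle.close()


def filter_best_alignment(records: Iterable[GafRecord]) -> list[GafRecord]:
    """Keep at most one record per read name.

    Best = highest residue-match count, ties broken by mapping quality,
    then by lexicographically smallest path string — fully deterministic.
    Output preserves the order of first appearance of each read.
    """
    best: dict[str, GafRecord] = {}
    order: list[str] = []
    for rec in records:
        cur = best.get(rec.name)
        if cur is None:
            best[rec.name] = rec
            order.append(rec.name)
            continue
        if (-rec.matches, -rec.mapq, rec.path_str) < (-cur.matches, -cur.mapq, cur.path_str):
            best[rec.name] = rec
    return [best[name] for name in order]
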