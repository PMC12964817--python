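"""Per-node coverage from graph alignments, normalization and genotype calls.

The structural-variant genotype of a short-read sample is read off the
depth of its alignments over the variant's nodes: per-base coverage over
the node set, divided by the sample's overall sequencing depth, sits near
0 for non-carriers, 0.5 for heterozygous carriers and 1.0 for homozygous
carriers (per carried copy), with values above the diploid band indicating
duplicated sequence.

Coverage accumulation assigns each record's aligned span
``[path_start, path_end)`` to nodes by intersecting it with the node
intervals along the record's walk — the per-node base counting a
gafpack-style tool performs. Soft-clipped read portions never enter the
span, so only aligned bases count.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping

from .gaf import GafRecord
from .graph import VariationGraph

__all__ = [
    "NodeCoverageTable",
    "NormalizedCoverage",
    "GenotypeCall",
    "accumulate_node_coverage",
    "build_coverage_table",
    "estimate_sample_depth",
    "normalized_region_coverage",
    "call_genotype",
]


def accumulate_node_coverage(
    records: Iterable[GafRecord],
    graph: VariationGraph,
    mode: str = "bases",
) -> dict[str, int]:
    """Accumulate one sample's aligned bases (or traversals) per node.

    For every record the aligned span ``[pstart, pend)`` is intersected
    with each step's node interval along the walk; the overlap length is
    added to that node (``mode="bases"``) or counted once per overlapped
    step (``mode="traversals"``). Repeated traversals of a node within one
    walk accumulate separately, so the per-record total is exactly
    ``pend - pstart`` in base mode.
    """
    if mode not in {"bases", "traversals"}:
        raise ValueError(f"unknown mode {mode!r}")
    counts: dict[str, int] = {}
    nodes = graph.nodes
    for rec in records:
        offset = 0
        for node_id, _rev in rec.path:
            info = nodes.get(node_id)
            if info is None:
                raise ValueError(
                    f"read {rec.name!r} walks unknown node {node_id!r}"
                )
            lo = max(rec.pstart, offset)
            hi = min(rec.pend, offset + info.length)
            if lo < hi:
                counts[node_id] = counts.get(node_id, 0) + (
                    hi - lo if mode == "bases" else 1
                )
            offset += info.length
        if offset != rec.path_len:
            raise ValueError(
                f"read {rec.name!r}: declared path length {rec.path_len} != "
                f"sum of node lengths {offset}"
            )
    return counts


@dataclass
class NodeCoverageTable:
    """Per-sample, per-node aligned-base counts."""

    counts: dict[str, dict[str, int]]  # sample -> node -> bases

    @property
    def total_bases(self) -> dict[str, int]:
        return {s: sum(c.values()) for s, c in self.counts.items()}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts).fillna(0).astype(int).rename_axis("node")


def build_coverage_table(
    records_by_sample: Mapping[str, Iterable[GafRecord]],
    graph: VariationGraph,
    mode: str = "bases",
) -> NodeCoverageTable:
    return NodeCoverageTable(
        counts={
            sample: accumulate_node_coverage(recs, graph, mode=mode)
            for sample, recs in records_by_sample.items()
        }
    )


def estimate_sample_depth(
    counts: Mapping[str, int],
    graph: VariationGraph,
    core_nodes: Iterable[str],
    override: float | None = None,
) -> float:
    """Sequencing-depth estimate: median per-base coverage over core nodes.

    Core nodes are present in every haplotype, so their per-base coverage is
    insensitive to the variant's genotype; the median is robust to the odd
    repeat-inflated node. An explicit ``override`` (e.g. a known genome-wide
    depth) is used verbatim when given.
    """
    if override is not None:
        if override <= 0:
            raise ValueError("depth override must be > 0")
        return float(override)
    core_nodes = list(core_nodes)
    if not core_nodes:
        raise ValueError("empty core node set and no depth override")
    return float(
        median(counts.get(n, 0) / graph.node_length(n) for n in core_nodes)
    )


@dataclass
class NormalizedCoverage:
    """Region coverage normalized over sequencing depth and region length."""

    sample: str
    region_id: str
    raw: float  # per-base coverage over the node set
    depth: float  # sample sequencing-depth estimate
    normalized: float  # raw / depth


def normalized_region_coverage(
    counts: Mapping[str, int],
    graph: VariationGraph,
    node_set: Iterable[str],
    depth: float,
    sample: str = "",
    region_id: str = "",
) -> NormalizedCoverage:
    """Per-base coverage over ``node_set`` divided by the sample depth."""
    node_set = list(node_set)
    if not node_set:
        raise ValueError("node set is empty")
    if depth <= 0:
        raise ValueError(f"depth must be > 0, got {depth}")
    total_len = sum(graph.node_length(n) for n in node_set)
    raw = sum(counts.get(n, 0) for n in node_set) / total_len
    return NormalizedCoverage(
        sample=sample,
        region_id=region_id,
        raw=raw,
        depth=depth,
        normalized=raw / depth,
    )


@dataclass
class GenotypeCall:
    """Per-sample SV state derived from normalized coverage.

    ``dosage`` is ``normalized / copies_per_allele`` — the statistic the
    thresholds classify, sitting near 0 / 0.5 / 1.0 for absent / het / hom
    when each carrier allele contributes ``copies_per_allele`` repeat
    copies. ``copy_number`` estimates total SV copies across the diploid
    genome as ``round(2 x normalized)`` (half-even).
    """

    sample: str
    region: str
    normalized: float
    dosage: float
    call: str  # absent | het | hom | dup
    copy_number: int


def call_genotype(
    norm: NormalizedCoverage,
    t_absent: float = 0.25,
    t_het_hi: float = 0.75,
    t_dup: float = 1.5,
    copies_per_allele: float = 1.0,
) -> GenotypeCall:
    """Threshold a normalized-coverage value into a genotype call.

    Bands are half-open with boundary values falling into the upper class:
    dosage < ``t_absent`` is absent, ``[t_absent, t_het_hi)`` het,
    ``[t_het_hi, t_dup)`` hom, and >= ``t_dup`` dup. The defaults sit
    symmetrically around the expected 0 / 0.5 / 1.0 states, with the dup
    boundary at the upper edge of the diploid band (1.50).
    """
    if not (0 < t_absent < t_het_hi < t_dup):
        raise ValueError(
            f"thresholds must be strictly increasing and positive: "
            f"{t_absent}, {t_het_hi}, {t_dup}"
        )
    if copies_per_allele <= 0:
        raise ValueError("copies_per_allele must be > 0")
    dosage = norm.normalized / copies_per_allele
    if dosage < t_absent:
        call = "absent"
    elif dosage < t_het_hi:
        call = "het"
    elif dosage < t_dup:
        call = "hom"
    else:
        call = "dup"
    return GenotypeCall(
        sample=norm.sample,
        region=norm.region_id,
        normalized=norm.normalized,
        dosage=dosage,
        call=call,
        copy_number=round(2 * norm.normalized),
    )
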