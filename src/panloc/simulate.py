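"""Synthetic cohorts with a known structural variant: the truth oracle.

The generator emulates the statistical structure the analysis assumes:

* a linear backbone haplotype shared by everyone, into which carrier
  haplotypes insert ``sv_copies`` identical repeat units at a fixed
  breakpoint (defaults 3 x 2,300 bp, a ~7 kb tandem insertion) — modelling
  copy number as repeated traversals of shared repeat-unit nodes, so extra
  copies manifest as elevated coverage rather than divergent sequence;
* a dominant carrier -> white-headed phenotype map (one carried allele
  suffices);
* private substitution SNPs per haplotype (no indels, keeping truth
  coordinates exact);
* uniform single-end short-read sampling at a configurable depth, with
  per-read truth placements emitted directly as graph alignments (GAF);
* assembly-vs-reference alignments (PAF with cg CIGAR) whose carrier
  records contain the insertion;
* a translocation-bearing contig whose segment order reproduces the
  rearrangement signature of the serial chromosome 6 <-> 29 translocations
  (the downstream "DE" segment repositioned upstream of the insertion site).

Determinism: one explicit seed drives everything; per-sample and per-read
randomness uses sub-streams derived from (seed, stream index), so adding
samples never perturbs earlier samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .gaf import GafRecord
from .graph import VariationGraph
from .intervals import GenomicInterval
from .paf import PafRecord
from .projection import TranslocationBlock

__all__ = [
    "SimConfig",
    "Haplotype",
    "SampleTruth",
    "ReadTruth",
    "SimTruth",
    "Cohort",
    "TranslocationSim",
    "simulate_haplotypes",
    "emit_truth_graph",
    "simulate_reads",
    "emit_paf",
    "simulate_translocation_contig",
    "simulate_cohort",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

#: Breed labels cycled over carrier / non-carrier samples. The white-headed
#: list mirrors the breeds in which the variant segregates; the colored list
#: provides the contrast group.
WHITE_BREEDS = ("Montbeliarde", "Normande", "Abondance", "Simmental", "Hereford")
COLORED_BREEDS = ("Holstein", "Charolaise", "Limousine", "Aubrac", "Tarentaise")

SV_UNIT_NODE = "sv_unit"
REFERENCE_NAME = "backbone"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults model a 30 kb locus with a 3 x 2.3 kb (~7 kb) tandem insertion
    at its midpoint, 40 diploid samples (12 carrier, 28 non-carrier),
    150 bp single-end reads at 30-fold coverage, a 0.1 % substitution error
    rate and 0.05 %/bp private SNPs per haplotype.
    """

    seed: int = 0
    backbone_length: int = 30_000
    sv_breakpoint: int = 15_000
    sv_unit_length: int = 2_300
    sv_copies: int = 3
    n_carrier_samples: int = 12
    n_noncarrier_samples: int = 28
    carrier_zygosity_probs: tuple[float, float] = (0.5, 0.5)  # (het, hom)
    read_length: int = 150
    depth: float = 30.0
    substitution_error_rate: float = 0.001
    snp_rate: float = 0.0005

    def validate(self) -> None:
        for name in ("backbone_length", "sv_unit_length", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sv_copies < 1:
            raise ValueError("sv_copies must be >= 1")
        if not (0 < self.sv_breakpoint < self.backbone_length):
            raise ValueError("sv_breakpoint must lie strictly inside the backbone")
        if self.sv_breakpoint + self.read_length >= self.backbone_length:
            raise ValueError(
                "sv_breakpoint + read_length must be < backbone_length"
            )
        if self.n_carrier_samples < 0 or self.n_noncarrier_samples < 0:
            raise ValueError("n_carrier_samples/n_noncarrier_samples must be >= 0")
        probs = self.carrier_zygosity_probs
        if len(probs) != 2 or any(not (0 <= p <= 1) for p in probs):
            raise ValueError("carrier_zygosity_probs must be two probabilities in [0,1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("carrier_zygosity_probs must sum to 1")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        for name in ("substitution_error_rate", "snp_rate"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be a probability in [0,1]")


@dataclass
class Haplotype:
    """One simulated haplotype: an ordered segment composition and its sequence."""

    name: str
    composition: list[tuple[str, str]] | None  # (segment id, segment sequence)
    sequence: str
    carrier: bool = False


@dataclass
class SampleTruth:
    sample: str
    breed: str
    phenotype: str  # white | colored
    genotype: str  # absent | het | hom
    haplotypes: tuple[str, str]


@dataclass
class ReadTruth:
    name: str
    sample: str
    haplotype: str
    start: int  # offset into the haplotype sequence


@dataclass
class SimTruth:
    """Everything the acceptance oracle needs: per-sample and per-read truth."""

    seed: int
    samples: dict[str, SampleTruth]
    segments: dict[str, str]  # segment id -> sequence
    sv_nodes: tuple[str, ...]
    reads: dict[str, list[ReadTruth]] = field(default_factory=dict)

    @property
    def genotypes(self) -> dict[str, str]:
        return {s: t.genotype for s, t in self.samples.items()}

    @property
    def phenotypes(self) -> dict[str, str]:
        return {s: t.phenotype for s, t in self.samples.items()}

    @property
    def carriers(self) -> frozenset[str]:
        return frozenset(s for s, t in self.samples.items() if t.genotype != "absent")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "sample": t.sample,
                    "breed": t.breed,
                    "phenotype": t.phenotype,
                    "genotype": t.genotype,
                }
                for t in self.samples.values()
            ]
        )


def _sample_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def simulate_haplotypes(
    config: SimConfig,
) -> tuple[str, list[Haplotype], SimTruth]:
    """Draw the backbone, the SV unit, and two haplotypes per sample.

    Carrier samples are het or hom per ``carrier_zygosity_probs`` (the
    first haplotype carries the insertion in hets). Private SNPs are drawn
    per haplotype over backbone coordinates only, so every carrier shares
    byte-identical SV units and the copy-number signal stays clean.

    Segment compositions are built over a single global segmentation of the
    backbone (split at the SV breakpoint and at every SNP site across the
    whole cohort), which is what lets :func:`emit_truth_graph` join all
    haplotypes into one graph.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    backbone = _random_seq(rng, config.backbone_length)
    unit = _random_seq(rng, config.sv_unit_length)

    n_total = config.n_carrier_samples + config.n_noncarrier_samples
    sample_names = [f"S{i:03d}" for i in range(n_total)]

    # phase 1: genotypes and per-haplotype SNP draws
    plan: list[tuple[str, str, list[tuple[bool, dict[int, str]]]]] = []
    for idx, sample in enumerate(sample_names):
        srng = _sample_rng(config.seed, idx)
        is_carrier = idx < config.n_carrier_samples
        if is_carrier:
            genotype = "het" if srng.random() < config.carrier_zygosity_probs[0] else "hom"
        else:
            genotype = "absent"
        haps: list[tuple[bool, dict[int, str]]] = []
        carry = {"absent": (False, False), "het": (True, False), "hom": (True, True)}[genotype]
        for hap_carries in carry:
            positions = np.flatnonzero(srng.random(config.backbone_length) < config.snp_rate)
            snps: dict[int, str] = {}
            for p in positions:
                orig = _CODE[ord(backbone[p])]
                alt = (orig + 1 + srng.integers(0, 3)) % 4
                snps[int(p)] = chr(_BASES[alt])
            haps.append((hap_carries, snps))
        plan.append((sample, genotype, haps))

    # phase 2: global segmentation at the breakpoint and every SNP site
    site_set = {p for _, _, haps in plan for _, snps in haps for p in snps}
    breaks = sorted(
        {0, config.sv_breakpoint, config.backbone_length}
        | site_set
        | {p + 1 for p in site_set}
    )
    segment_ids: list[tuple[int, str, str]] = []  # (start, id, seq) backbone order
    for x, y in zip(breaks, breaks[1:]):
        if x in site_set:
            segment_ids.append((x, f"b{x}", backbone[x]))
        else:
            segment_ids.append((x, f"b{x}_{y}", backbone[x:y]))

    segments: dict[str, str] = {sid: seq for _, sid, seq in segment_ids}
    segments[SV_UNIT_NODE] = unit

    haplotypes: list[Haplotype] = []
    truth_samples: dict[str, SampleTruth] = {}
    n_carrier_seen = 0
    for idx, (sample, genotype, haps) in enumerate(plan):
        breed_pool = WHITE_BREEDS if genotype != "absent" else COLORED_BREEDS
        pool_idx = idx if genotype != "absent" else idx - config.n_carrier_samples
        breed = breed_pool[pool_idx % len(breed_pool)]
        hap_names = []
        for hap_no, (carries, snps) in enumerate(haps, start=1):
            name = f"{sample}#{hap_no}"
            composition: list[tuple[str, str]] = []
            for start, sid, seq in segment_ids:
                if start == config.sv_breakpoint and carries:
                    composition.extend([(SV_UNIT_NODE, unit)] * config.sv_copies)
                if start in snps:
                    alt = snps[start]
                    composition.append((f"b{start}:{alt}", alt))
                    segments.setdefault(f"b{start}:{alt}", alt)
                else:
                    composition.append((sid, seq))
            sequence = "".join(seq for _, seq in composition)
            haplotypes.append(
                Haplotype(name=name, composition=composition, sequence=sequence, carrier=carries)
            )
            hap_names.append(name)
        truth_samples[sample] = SampleTruth(
            sample=sample,
            breed=breed,
            phenotype="white" if genotype != "absent" else "colored",
            genotype=genotype,
            haplotypes=(hap_names[0], hap_names[1]),
        )

    truth = SimTruth(
        seed=config.seed,
        samples=truth_samples,
        segments=segments,
        sv_nodes=(SV_UNIT_NODE,),
    )
    return backbone, haplotypes, truth


def emit_truth_graph(haplotypes: Sequence[Haplotype]) -> VariationGraph:
    """Join haplotype compositions into one variation graph with P-line paths.

    Shared backbone segments become shared nodes; the SV unit is one node
    traversed ``sv_copies`` times by each carrier path. Walking any path
    reproduces that haplotype's sequence exactly.
    """
    graph = VariationGraph()
    for hap in haplotypes:
        if not hap.composition:
            raise ValueError(f"haplotype {hap.name!r} has unknown composition")
        for sid, seq in hap.composition:
            if sid not in graph.nodes:
                graph.add_node(sid, sequence=seq)
            elif graph.nodes[sid].sequence != seq:
                raise ValueError(f"segment {sid!r} has conflicting sequences")
    for hap in haplotypes:
        graph.add_path(hap.name, [(sid, False) for sid, _ in hap.composition])
    return graph


@dataclass
class SampleReadSet:
    sample: str
    fastq: list[tuple[str, str, str]]  # (name, sequence, quality)
    gaf: list[GafRecord]


def simulate_reads(
    truth: SimTruth,
    haplotypes: Mapping[str, Haplotype] | Sequence[Haplotype],
    config: SimConfig,
) -> dict[str, SampleReadSet]:
    """Uniform single-end reads per haplotype at depth/2, with truth GAF.

    Read counts are Poisson around ``len(hap) * depth / 2 / read_length``;
    starts are uniform; substitution errors at the configured rate change
    bases but never placements. Each truth-GAF record's path is the
    sub-walk of the haplotype's graph path covering the read, with
    path-coordinate start/end, so per-node coverage accumulated from these
    records is exact by construction.
    """
    config.validate()
    if config.depth <= 0:
        raise ValueError("depth must be > 0")
    if isinstance(haplotypes, Mapping):
        hap_by_name = dict(haplotypes)
    else:
        hap_by_name = {h.name: h for h in haplotypes}
    out: dict[str, SampleReadSet] = {}
    qual = "I" * config.read_length
    sample_list = list(truth.samples.values())
    for sidx, st in enumerate(sample_list):
        fastq: list[tuple[str, str, str]] = []
        gaf: list[GafRecord] = []
        truth.reads[st.sample] = []
        for hap_no, hap_name in enumerate(st.haplotypes):
            hap = hap_by_name[hap_name]
            hlen = len(hap.sequence)
            if hlen < config.read_length:
                raise ValueError(f"haplotype {hap_name!r} shorter than read length")
            rng = _sample_rng(config.seed, 10_000 + 2 * sidx + hap_no)
            n_reads = int(rng.poisson(hlen * config.depth / 2 / config.read_length))
            starts = np.sort(rng.integers(0, hlen - config.read_length + 1, n_reads))

            arr = np.frombuffer(hap.sequence.encode(), dtype=np.uint8)
            mat = arr[starts[:, None] + np.arange(config.read_length)]
            if config.substitution_error_rate > 0 and n_reads:
                err = rng.random(mat.shape) < config.substitution_error_rate
                n_err_pos = int(err.sum())
                if n_err_pos:
                    codes = _CODE[mat[err]]
                    mat = mat.copy()
                    mat[err] = _BASES[(codes + rng.integers(1, 4, n_err_pos)) % 4]
                n_err = err.sum(axis=1)
            else:
                n_err = np.zeros(n_reads, dtype=int)

            seg_lens = np.array([len(seq) for _, seq in hap.composition])
            cum = np.concatenate([[0], np.cumsum(seg_lens)])
            tokens = [sid for sid, _ in hap.composition]
            first = np.searchsorted(cum, starts, side="right") - 1
            last = np.searchsorted(cum, starts + config.read_length - 1, side="right") - 1
            for i in range(n_reads):
                start = int(starts[i])
                name = f"{hap_name}|r{i}"
                seq = mat[i].tobytes().decode()
                fastq.append((name, seq, qual))
                f, l = int(first[i]), int(last[i])
                path = tuple((tokens[j], False) for j in range(f, l + 1))
                plen = int(cum[l + 1] - cum[f])
                pstart = start - int(cum[f])
                matches = config.read_length - int(n_err[i])
                gaf.append(
                    GafRecord(
                        name=name,
                        qlen=config.read_length,
                        qstart=0,
                        qend=config.read_length,
                        strand="+",
                        path=path,
                        path_len=plen,
                        pstart=pstart,
                        pend=pstart + config.read_length,
                        matches=matches,
                        block_len=config.read_length,
                        mapq=60,
                    )
                )
                truth.reads[st.sample].append(
                    ReadTruth(name=name, sample=st.sample, haplotype=hap_name, start=start)
                )
        out[st.sample] = SampleReadSet(sample=st.sample, fastq=fastq, gaf=gaf)
    return out


def emit_paf(haplotypes: Sequence[Haplotype], backbone_length: int) -> list[PafRecord]:
    """Assembly-vs-reference PAF, one record per haplotype, with cg CIGAR.

    Non-carriers align end-to-end as a single match-only block (SNPs are
    mismatches inside M); carriers contain one insertion of
    ``sv_copies x unit`` at the breakpoint. Coordinates are 0-based
    half-open per the PAF convention.
    """
    records: list[PafRecord] = []
    for hap in haplotypes:
        if not hap.composition:
            raise ValueError(f"haplotype {hap.name!r} has unknown composition")
        ops: list[list] = []  # [length, op]
        mismatches = 0
        for sid, seq in hap.composition:
            if sid == SV_UNIT_NODE:
                op = "I"
            else:
                op = "M"
                if ":" in sid:
                    mismatches += len(seq)
            if ops and ops[-1][1] == op:
                ops[-1][0] += len(seq)
            else:
                ops.append([len(seq), op])
        cigar = "".join(f"{n}{op}" for n, op in ops)
        qlen = len(hap.sequence)
        block = sum(n for n, _ in ops)
        records.append(
            PafRecord(
                qname=hap.name,
                qlen=qlen,
                qstart=0,
                qend=qlen,
                strand="+",
                tname=REFERENCE_NAME,
                tlen=backbone_length,
                tstart=0,
                tend=backbone_length,
                matches=backbone_length - mismatches,
                block_len=block,
                mapq=60,
                tags={"cg": cigar},
            )
        )
    return records


@dataclass
class TranslocationSim:
    """A toy two-chromosome reference plus a rearranged contig.

    The contig carries a chr29 flank, then the *downstream* chr6 segment
    (DE), then the upstream chr6 segment (AD), then chr29 again — the
    segment-order signature of the serial translocation: segment DE
    repositioned upstream of the insertion on chromosome 29.
    """

    reference: dict[str, str]
    contigs: dict[str, str]
    paf: list[PafRecord]
    truth_signature: list[TranslocationBlock]
    control_signature: list[TranslocationBlock]
    target: GenomicInterval


def simulate_translocation_contig(config: SimConfig) -> TranslocationSim:
    rng = _sample_rng(config.seed, 777)
    chr6 = _random_seq(rng, 40_000)
    chr29 = _random_seq(rng, 40_000)
    # chr6 blocks: AD = [10k, 22k), DE = [22k, 30k); chr29 flanks around 13k
    ad = (10_000, 22_000)
    de = (22_000, 30_000)
    fl_left = (5_000, 13_000)
    fl_right = (13_000, 21_000)
    contig = (
        chr29[fl_left[0] : fl_left[1]]
        + chr6[de[0] : de[1]]
        + chr6[ad[0] : ad[1]]
        + chr29[fl_right[0] : fl_right[1]]
    )
    control = chr6[ad[0] : de[1]]

    def _rec(qname, qlen, qstart, qend, tname, tstart, tend):
        n = qend - qstart
        return PafRecord(
            qname=qname,
            qlen=qlen,
            qstart=qstart,
            qend=qend,
            strand="+",
            tname=tname,
            tlen=40_000,
            tstart=tstart,
            tend=tend,
            matches=n,
            block_len=n,
            mapq=60,
            tags={"cg": f"{n}M"},
        )

    clen = len(contig)
    blocks = [
        ("chr29", fl_left, 0),
        ("chr6", de, fl_left[1] - fl_left[0]),
        ("chr6", ad, fl_left[1] - fl_left[0] + de[1] - de[0]),
        ("chr29", fl_right, clen - (fl_right[1] - fl_right[0])),
    ]
    paf = [
        _rec("tlc_contig", clen, qoff, qoff + (t1 - t0), chrom, t0, t1)
        for chrom, (t0, t1), qoff in blocks
    ]
    paf.append(_rec("colinear_contig", len(control), 0, len(control), "chr6", ad[0], de[1]))
    truth_signature = [
        TranslocationBlock(
            chrom=chrom,
            interval=GenomicInterval(chrom, t0, t1, "+"),
            strand="+",
            qstart=qoff,
            qend=qoff + (t1 - t0),
        )
        for chrom, (t0, t1), qoff in blocks
    ]
    control_signature = [
        TranslocationBlock(
            chrom="chr6",
            interval=GenomicInterval("chr6", ad[0], de[1], "+"),
            strand="+",
            qstart=0,
            qend=len(control),
        )
    ]
    return TranslocationSim(
        reference={"chr6": chr6, "chr29": chr29},
        contigs={"tlc_contig": contig, "colinear_contig": control},
        paf=paf,
        truth_signature=truth_signature,
        control_signature=control_signature,
        target=GenomicInterval("chr6", ad[0], de[1]),
    )


@dataclass
class Cohort:
    """A fully simulated cohort: sequences, truth graph, alignments, truth."""

    config: SimConfig
    backbone: str
    haplotypes: list[Haplotype]
    graph: VariationGraph
    paf: list[PafRecord]
    truth: SimTruth

    @property
    def haplotypes_by_name(self) -> dict[str, Haplotype]:
        return {h.name: h for h in self.haplotypes}

    def reads(self) -> dict[str, SampleReadSet]:
        return simulate_reads(self.truth, self.haplotypes_by_name, self.config)


def simulate_cohort(config: SimConfig) -> Cohort:
    """Convenience wrapper: haplotypes + truth graph + PAF in one call."""
    backbone, haplotypes, truth = simulate_haplotypes(config)
    graph = emit_truth_graph(haplotypes)
    paf = emit_paf(haplotypes, config.backbone_length)
    return Cohort(
        config=config,
        backbone=backbone,
        haplotypes=haplotypes,
        graph=graph,
        paf=paf,
        truth=truth,
    )
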