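"""End-to-end orchestration: simulate -> project -> classify -> detect-sv ->
genotype -> associate, with a fixed output layout and a JSON run summary.

A run consumes either a simulation block (the synthetic cohort with known
truth) or real input files (GFA graph, per-sample GAF alignments, PAF,
phenotype TSV) — never both. Outputs land under fixed subdirectories
(``sim/``, ``projection/``, ``graph/``, ``genotypes/``, ``association/``,
``summary.json``) so downstream tooling can address files by name. Reruns
with an identical config reproduce identical outputs byte for byte; only
the elapsed-time entries of the summary differ.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from ._util import write_fasta, write_fastq
from .association import (
    breed_carrier_summary,
    carrier_phenotype_table,
    dominance_concordance,
    fisher_exact_two_sided,
)
from .coverage import (
    accumulate_node_coverage,
    call_genotype,
    estimate_sample_depth,
    normalized_region_coverage,
)
from .gaf import filter_best_alignment, parse_gaf, write_gaf
from .graph import (
    classify_nodes,
    detect_differential_subregions,
    extract_subgraph,
    graph_stats,
    parse_gfa,
    path_node_depth,
    write_gfa,
)
from .intervals import GenomicInterval, parse_region
from .paf import parse_paf, write_paf
from .projection import (
    admit_additional_contigs,
    detect_translocation_signatures,
    project_interval,
)
from .simulate import REFERENCE_NAME, SimConfig, simulate_cohort, simulate_translocation_contig

logger = logging.getLogger("panloc.pipeline")

__all__ = ["RunConfig", "RunSummary", "PipelineError", "validate_config", "run_end_to_end"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    outdir: Path
    simulate: SimConfig | None = None
    inputs: dict[str, Any] | None = None  # gfa, gaf (dir), paf, phenotypes, backbone, region
    write_fastq: bool = False
    min_len: int = 10_000
    min_frac: float = 0.80
    min_block: int = 5_000
    sv_min_len: int = 1_000
    min_carriers: int = 2
    max_gap: int = 5
    t_absent: float = 0.25
    t_het_hi: float = 0.75
    t_dup: float = 1.5
    depth_override: float | None = None
    delimiter: str = "#"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(
            outdir=Path(raw.pop("outdir", "panloc_run")),
            simulate=SimConfig(**sim) if sim is not None else None,
            **raw,
        )
        return cfg

    def canonical(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(d["outdir"])
        return d

    @property
    def config_hash(self) -> str:
        # hash the analytical parameters only, so the same analysis written
        # to a different directory keeps the same identity
        d = self.canonical()
        d.pop("outdir", None)
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """List every violated invariant; an empty list means the config is runnable."""
    findings: list[str] = []
    has_sim = config.simulate is not None
    has_inputs = bool(config.inputs)
    if has_sim == has_inputs:
        findings.append(
            "exactly one of a simulation block and real inputs must be given"
        )
    if has_sim:
        try:
            config.simulate.validate()
        except ValueError as exc:
            findings.append(f"simulation config: {exc}")
    if has_inputs:
        for key in ("gfa", "paf", "phenotypes"):
            path = config.inputs.get(key)
            if path is not None and not Path(path).exists():
                findings.append(f"input file missing: {path}")
        gaf_dir = config.inputs.get("gaf")
        if gaf_dir is not None:
            p = Path(gaf_dir)
            if not p.exists():
                findings.append(f"input file missing: {gaf_dir}")
            elif p.is_dir() and not list(p.glob("*.gaf")):
                findings.append(f"no *.gaf files under {gaf_dir}")
        region = config.inputs.get("region")
        if region is not None:
            try:
                parse_region(str(region))
            except ValueError as exc:
                findings.append(str(exc))
    if not (0 < config.t_absent < config.t_het_hi < config.t_dup):
        findings.append(
            f"genotype thresholds must be strictly increasing: "
            f"{config.t_absent}, {config.t_het_hi}, {config.t_dup}"
        )
    if config.min_frac < 0 or config.min_frac > 1:
        findings.append(f"min_frac must be in [0,1], got {config.min_frac}")
    for name in ("min_len", "min_block", "sv_min_len", "min_carriers", "max_gap"):
        if getattr(config, name) < 0:
            findings.append(f"{name} must be >= 0")
    if config.depth_override is not None and config.depth_override <= 0:
        findings.append(f"depth_override must be > 0, got {config.depth_override}")
    return findings


@dataclass
class RunSummary:
    config_hash: str
    stages: dict[str, dict] = field(default_factory=dict)
    graph: dict = field(default_factory=dict)
    subregions: list[dict] = field(default_factory=list)
    genotypes: list[dict] = field(default_factory=list)
    association: dict = field(default_factory=dict)
    failed_stage: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def run_end_to_end(config: RunConfig) -> RunSummary:
    """Run every stage, writing outputs under ``config.outdir``.

    The first failing stage halts the run: the summary (with the failure
    marked) is still written, then a :class:`PipelineError` naming the
    stage and cause is raised.
    """
    findings = validate_config(config)
    if findings:
        raise PipelineError("invalid config: " + "; ".join(findings))
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary = RunSummary(config_hash=config.config_hash)
    logger.info("run config hash %s; parameters: %s", config.config_hash, config.canonical())

    state: dict[str, Any] = {}
    sim_mode = config.simulate is not None
    stages = [
        ("simulate", _stage_simulate) if sim_mode else ("ingest", _stage_ingest),
        ("project", _stage_project),
        ("classify", _stage_classify),
        ("detect_sv", _stage_detect_sv),
        ("genotype", _stage_genotype),
        ("associate", _stage_associate),
    ]
    for name, fn in stages:
        logger.info("=== stage %s ===", name)
        t0 = time.perf_counter()
        try:
            record = fn(config, out, state, summary)
        except Exception as exc:
            summary.failed_stage = name
            summary.stages[name] = {"error": str(exc)}
            summary.write(out / "summary.json")
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        record = record or {}
        record["elapsed_s"] = round(time.perf_counter() - t0, 3)
        summary.stages[name] = record
    summary.write(out / "summary.json")
    return summary


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, out: Path, state: dict, summary: RunSummary) -> dict:
    sim = out / "sim"
    (sim / "reads").mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config.simulate)
    write_fasta([(REFERENCE_NAME, cohort.backbone)], sim / "backbone.fa")
    write_fasta([(h.name, h.sequence) for h in cohort.haplotypes], sim / "haplotypes.fa")
    write_gfa(cohort.graph, sim / "graph.gfa")
    write_paf(cohort.paf, sim / "alignments.paf")
    _write_tsv(cohort.truth.to_frame(), sim / "truth_samples.tsv")
    reads = cohort.reads()
    for sample, rset in reads.items():
        write_gaf(rset.gaf, sim / "reads" / f"{sample}.gaf")
        if config.write_fastq:
            write_fastq(rset.fastq, sim / "reads" / f"{sample}.fastq")
    state["cohort"] = cohort
    state["gaf_dir"] = sim / "reads"
    state["gfa_path"] = sim / "graph.gfa"
    state["paf_path"] = sim / "alignments.paf"
    state["region"] = GenomicInterval(REFERENCE_NAME, 0, config.simulate.backbone_length)
    state["phenotypes"] = cohort.truth.to_frame()
    state["truth"] = cohort.truth
    # the ordering backbone: first non-carrier haplotype path, else first path
    backbone = next(
        (h.name for h in cohort.haplotypes if not h.carrier),
        cohort.haplotypes[0].name,
    )
    state["backbone_path"] = backbone
    return {
        "n_samples": len(cohort.truth.samples),
        "n_haplotypes": len(cohort.haplotypes),
        "n_reads": sum(len(r.gaf) for r in reads.values()),
        "seed": config.simulate.seed,
    }


def _stage_ingest(config: RunConfig, out: Path, state: dict, summary: RunSummary) -> dict:
    inputs = config.inputs
    state["gfa_path"] = inputs.get("gfa")
    state["paf_path"] = inputs.get("paf")
    state["gaf_dir"] = inputs.get("gaf")
    state["backbone_path"] = inputs.get("backbone")
    if inputs.get("region"):
        state["region"] = parse_region(str(inputs["region"]))
    if inputs.get("phenotypes"):
        state["phenotypes"] = pd.read_csv(inputs["phenotypes"], sep="\t")
    return {"inputs": {k: str(v) for k, v in inputs.items()}}


def _stage_project(config: RunConfig, out: Path, state: dict, summary: RunSummary) -> dict:
    proj = out / "projection"
    proj.mkdir(parents=True, exist_ok=True)
    record: dict[str, Any] = {}
    if state.get("paf_path") and state.get("region") is not None:
        with open(state["paf_path"]) as handle:
            records = parse_paf(handle)
        region = state["region"]
        segments = project_interval(records, region)
        bed = pd.DataFrame(
            [
                {
                    "contig": s.image.chrom,
                    "start": s.image.start,
                    "end": s.image.end,
                    "source": str(s.source),
                    "strand": s.image.strand,
                    "identity": round(s.identity, 6),
                    "approximate": s.approximate,
                }
                for s in segments
            ]
        )
        _write_tsv(bed, proj / "segments.bed")
        contig_lengths = {r.qname: r.qlen for r in records}
        admissions = admit_additional_contigs(
            segments, contig_lengths, min_len=config.min_len, min_frac=config.min_frac
        )
        _write_tsv(
            pd.DataFrame([dataclasses.asdict(a) for a in admissions]),
            proj / "admissions.tsv",
        )
        record["n_paf_records"] = len(records)
        record["n_segments"] = len(segments)
        record["n_admitted"] = sum(a.admitted for a in admissions)
    if state.get("cohort") is not None:
        tsim = simulate_translocation_contig(config.simulate)
        write_paf(tsim.paf, proj / "translocation.paf")
        signatures = detect_translocation_signatures(
            tsim.paf, tsim.target, min_block=config.min_block
        )
        rows = [
            {
                "contig": sig.contig,
                "n_blocks": len(sig.blocks),
                "multi_chromosome": sig.multi_chromosome,
                "non_colinear": sig.non_colinear,
                "blocks": ";".join(
                    f"{b.chrom}:{b.interval.start}-{b.interval.end}{b.strand}"
                    for b in sig.blocks
                ),
            }
            for sig in signatures
        ]
        _write_tsv(pd.DataFrame(rows), proj / "signatures.tsv")
        record["n_translocation_signatures"] = sum(
            1 for sig in signatures if sig.multi_chromosome or sig.non_colinear
        )
    return record


def _stage_classify(config: RunConfig, out: Path, state: dict, summary: RunSummary) -> dict:
    gdir = out / "graph"
    gdir.mkdir(parents=True, exist_ok=True)
    with open(state["gfa_path"]) as handle:
        graph = parse_gfa(handle)
    state["graph"] = graph
    depth_table = path_node_depth(graph, delimiter=config.delimiter)
    state["depth_table"] = depth_table
    classes = classify_nodes(depth_table)
    state["classes"] = classes
    frame = depth_table.to_frame()
    frame["length"] = [graph.node_length(n) for n in frame["node"]]
    frame["class"] = [classes.labels.get(n, "untraversed") for n in frame["node"]]
    _write_tsv(frame, gdir / "node_classes.tsv")
    stats = graph_stats(graph)
    summary.graph = {
        "n_nodes": stats.n_nodes,
        "n_edges": stats.n_edges,
        "total_bp": stats.total_bp,
        "n_paths": stats.n_paths,
        "class_counts": dict(classes.counts),
    }
    return {"n_nodes": stats.n_nodes, "n_paths": stats.n_paths}


def _stage_detect_sv(config: RunConfig, out: Path, state: dict, summary: RunSummary) -> dict:
    gdir = out / "graph"
    graph = state["graph"]
    backbone = state.get("backbone_path") or next(iter(graph.paths))
    calls = detect_differential_subregions(
        graph,
        state["depth_table"],
        backbone,
        min_total_len=config.sv_min_len,
        min_carriers=config.min_carriers,
        max_gap=config.max_gap,
        delimiter=config.delimiter,
    )
    state["subregion_calls"] = calls
    rows = [
        {
            "rank": i + 1,
            "n_nodes": len(c.nodes),
            "node_length": c.node_length,
            "inserted_length": c.inserted_length,
            "copy_number": round(c.copy_number, 3),
            "n_carriers": len(c.carriers),
            "carriers": ",".join(sorted(c.carriers)),
            "anchor": c.anchor,
            "nodes": ",".join(c.nodes),
        }
        for i, c in enumerate(calls)
    ]
    _write_tsv(pd.DataFrame(rows), gdir / "subregions.tsv")
    summary.subregions = rows
    if calls:
        sub = extract_subgraph(graph, calls[0].nodes, flank=50)
        write_gfa(sub, gdir / "subregion.gfa")
    return {"n_calls": len(calls), "backbone": backbone}


def _iter_gaf_files(gaf_dir) -> list[tuple[str, Path]]:
    p = Path(gaf_dir)
    if p.is_dir():
        return [(f.stem, f) for f in sorted(p.glob("*.gaf"))]
    return [(p.stem, p)]


def _stage_genotype(config: RunConfig, out: Path, state: dict, summary: RunSummary) -> dict:
    gdir = out / "genotypes"
    gdir.mkdir(parents=True, exist_ok=True)
    calls = state.get("subregion_calls") or []
    if not calls:
        _write_tsv(pd.DataFrame(), gdir / "calls.tsv")
        state["genotype_calls"] = {}
        return {"n_samples": 0, "note": "no subregion call; nothing to genotype"}
    top = calls[0]
    graph = state["graph"]
    classes = state["classes"]
    core = [n for n, label in classes.labels.items() if label == "core"]
    copies = max(1.0, round(top.copy_number))
    rows = []
    genotype_calls: dict[str, Any] = {}
    for sample, gaf_path in _iter_gaf_files(state["gaf_dir"]):
        with open(gaf_path) as handle:
            records = filter_best_alignment(parse_gaf(handle))
        counts = accumulate_node_coverage(records, graph)
        depth = estimate_sample_depth(counts, graph, core, override=config.depth_override)
        norm = normalized_region_coverage(
            counts, graph, top.nodes, depth, sample=sample, region_id="subregion_1"
        )
        call = call_genotype(
            norm,
            t_absent=config.t_absent,
            t_het_hi=config.t_het_hi,
            t_dup=config.t_dup,
            copies_per_allele=copies,
        )
        genotype_calls[sample] = call
        rows.append(
            {
                "sample": sample,
                "n_reads": len(records),
                "depth_estimate": round(depth, 4),
                "normalized": round(call.normalized, 4),
                "dosage": round(call.dosage, 4),
                "call": call.call,
                "copy_number": call.copy_number,
            }
        )
    frame = pd.DataFrame(rows)
    _write_tsv(frame, gdir / "calls.tsv")
    state["genotype_calls"] = genotype_calls
    summary.genotypes = rows
    return {"n_samples": len(rows), "copies_per_allele": copies}


def _stage_associate(config: RunConfig, out: Path, state: dict, summary: RunSummary) -> dict:
    adir = out / "association"
    adir.mkdir(parents=True, exist_ok=True)
    genotype_calls = state.get("genotype_calls") or {}
    phenotypes = state.get("phenotypes")
    if not genotype_calls or phenotypes is None:
        (adir / "report.md").write_text("No genotype calls or phenotypes available.\n")
        return {"note": "skipped: missing genotypes or phenotypes"}
    carriers = {s: c.call != "absent" for s, c in genotype_calls.items()}
    breed_summary = breed_carrier_summary(carriers, phenotypes)
    pheno_map = dict(zip(phenotypes["sample"], phenotypes["phenotype"]))
    table = carrier_phenotype_table(carriers, pheno_map)
    assoc = fisher_exact_two_sided(table)
    called = {s: c.call for s, c in genotype_calls.items()}
    concordance, discordant = dominance_concordance(called, pheno_map)
    result = {
        "p_value": assoc.p_value,
        "odds_ratio": assoc.odds_ratio,
        "haldane_corrected": assoc.haldane_corrected,
        "table": [[table.a, table.b], [table.c, table.d]],
        "dominance_concordance": concordance,
        "n_discordant": len(discordant),
    }
    truth = state.get("truth")
    if truth is not None:
        truth_geno = truth.genotypes
        agree = sum(called[s] == truth_geno[s] for s in called)
        result["genotype_concordance_with_truth"] = agree / len(called)
    summary.association = result
    _write_tsv(breed_summary.per_breed, adir / "per_breed.tsv")
    _write_tsv(breed_summary.totals, adir / "totals.tsv")
    lines = [
        "# Association report",
        "",
        "## Carriers per breed",
        "",
        breed_summary.per_breed.to_string(index=False),
        "",
        "## Totals per phenotype group",
        "",
        breed_summary.totals.to_string(index=False),
        "",
        f"Carrier x phenotype table (carrier&white, carrier&colored / "
        f"noncarrier&white, noncarrier&colored): "
        f"[[{table.a}, {table.b}], [{table.c}, {table.d}]]",
        f"Fisher exact two-sided p = {assoc.p_value:.3e}",
        f"Odds ratio = {assoc.odds_ratio:.3f}"
        + (" (Haldane-corrected: zero cell)" if assoc.haldane_corrected else ""),
        f"Dominance concordance = {concordance:.4f} "
        f"({len(discordant)} discordant: {', '.join(discordant) or 'none'})",
        "",
    ]
    if "genotype_concordance_with_truth" in result:
        lines.append(
            f"Genotype concordance with simulation truth = "
            f"{result['genotype_concordance_with_truth']:.4f}"
        )
        lines.append("")
    (adir / "report.md").write_text("\n".join(lines))
    return {"p_value": assoc.p_value, "dominance_concordance": concordance}
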