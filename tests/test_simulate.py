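"""The synthetic-data generator: determinism, composition, reads, PAF."""

import io
import math
from dataclasses import replace

import numpy as np
import pytest

from panloc._util import write_fasta
from panloc.graph import write_gfa
from panloc.paf import format_paf, parse_paf
from panloc.simulate import (
    Haplotype,
    SimConfig,
    emit_paf,
    emit_truth_graph,
    simulate_cohort,
    simulate_haplotypes,
    simulate_reads,
)

CLEAN = SimConfig(
    seed=5,
    backbone_length=6_000,
    sv_breakpoint=3_000,
    sv_unit_length=400,
    sv_copies=3,
    n_carrier_samples=2,
    n_noncarrier_samples=2,
    read_length=100,
    depth=20.0,
    substitution_error_rate=0.0,
    snp_rate=0.0,
)


def test_carrier_haplotype_length_arithmetic():
    cfg = replace(CLEAN, sv_unit_length=2_300, backbone_length=30_000, sv_breakpoint=15_000)
    _, haps, truth = simulate_haplotypes(cfg)
    for hap in haps:
        expected = cfg.backbone_length + (6_900 if hap.carrier else 0)
        assert len(hap.sequence) == expected


def test_noncarrier_equals_backbone_without_snps():
    backbone, haps, _ = simulate_haplotypes(CLEAN)
    for hap in haps:
        if not hap.carrier:
            assert hap.sequence == backbone


def test_same_seed_gives_byte_identical_outputs():
    outputs = []
    for _ in range(2):
        cohort = simulate_cohort(SimConfig(seed=9, n_carrier_samples=2,
                                           n_noncarrier_samples=2,
                                           backbone_length=4_000, sv_breakpoint=2_000,
                                           sv_unit_length=300, depth=8.0))
        fa, gfa = io.StringIO(), io.StringIO()
        write_fasta([(h.name, h.sequence) for h in cohort.haplotypes], fa)
        write_gfa(cohort.graph, gfa)
        paf = "\n".join(format_paf(r) for r in cohort.paf)
        reads = cohort.reads()
        from panloc.gaf import format_gaf

        gaf = "\n".join(format_gaf(r) for rset in reads.values() for r in rset.gaf)
        fq = "\n".join("\n".join(t) for rset in reads.values() for t in rset.fastq)
        outputs.append((fa.getvalue(), gfa.getvalue(), paf, gaf, fq))
    assert outputs[0] == outputs[1]


@pytest.mark.parametrize(
    "field,value,needle",
    [
        ("sv_copies", 0, "sv_copies"),
        ("depth", -1.0, "depth"),
        ("carrier_zygosity_probs", (0.7, 0.7), "sum to 1"),
        ("sv_breakpoint", 29_990, "read_length"),
        ("snp_rate", 1.5, "snp_rate"),
        ("backbone_length", 0, "backbone_length"),
    ],
)
def test_invalid_config_rejected_naming_field(field, value, needle):
    cfg = replace(SimConfig(), **{field: value})
    with pytest.raises(ValueError, match=needle):
        simulate_haplotypes(cfg)


# ---------------------------------------------------------------------------
# truth graph


def test_carrier_paths_traverse_sv_unit_sv_copies_times(small_cohort):
    g = small_cohort.graph
    sv = small_cohort.truth.sv_nodes[0]
    for hap in small_cohort.haplotypes:
        count = sum(1 for nid, _ in g.paths[hap.name] if nid == sv)
        assert count == (small_cohort.config.sv_copies if hap.carrier else 0)


def test_node_count_equals_distinct_segments(small_cohort):
    distinct = {sid for hap in small_cohort.haplotypes for sid, _ in hap.composition}
    assert set(small_cohort.graph.nodes) == distinct


def test_unknown_composition_rejected():
    with pytest.raises(ValueError, match="composition"):
        emit_truth_graph([Haplotype("x#1", None, "ACGT")])


def test_conflicting_segment_sequences_rejected():
    h1 = Haplotype("a#1", [("s", "AAAA")], "AAAA")
    h2 = Haplotype("b#1", [("s", "CCCC")], "CCCC")
    with pytest.raises(ValueError, match="conflict"):
        emit_truth_graph([h1, h2])


# ---------------------------------------------------------------------------
# reads


def test_read_count_matches_coverage_identity():
    """depth 30 over a 30 kb diploid locus at 150 bp -> ~6,000 reads."""
    cfg = SimConfig(seed=2, n_carrier_samples=0, n_noncarrier_samples=1, snp_rate=0.0)
    _, haps, truth = simulate_haplotypes(cfg)
    reads = simulate_reads(truth, haps, cfg)
    n = len(reads["S000"].gaf)
    assert abs(n - 6_000) < 5 * math.sqrt(6_000)


def test_error_free_reads_substring_match_their_haplotype(small_config):
    cfg = replace(CLEAN, seed=13)
    _, haps, truth = simulate_haplotypes(cfg)
    by_name = {h.name: h for h in haps}
    reads = simulate_reads(truth, haps, cfg)
    for sample, rset in reads.items():
        seqs = {name: seq for name, seq, _ in rset.fastq}
        for rt in truth.reads[sample]:
            hap = by_name[rt.haplotype]
            assert seqs[rt.name] == hap.sequence[rt.start : rt.start + cfg.read_length]


def test_truth_gaf_records_are_exact_subwalks(small_cohort, small_reads):
    g = small_cohort.graph
    for sample, rset in small_reads.items():
        for rec in rset.gaf[:100]:
            assert rec.pend - rec.pstart == small_cohort.config.read_length
            assert rec.path_len == sum(g.node_length(n) for n, _ in rec.path)
            rec.validate()


def test_mean_pileup_coverage_within_five_percent_of_depth():
    """Across 10 seeds, backbone pileup from truth placements averages ~depth."""
    means = []
    for seed in range(10):
        cfg = SimConfig(seed=seed, n_carrier_samples=0, n_noncarrier_samples=1,
                        backbone_length=6_000, sv_breakpoint=3_000,
                        sv_unit_length=300, read_length=100, depth=25.0, snp_rate=0.0)
        _, haps, truth = simulate_haplotypes(cfg)
        reads = simulate_reads(truth, haps, cfg)
        pileup = np.zeros(cfg.backbone_length)
        for rt in truth.reads["S000"]:
            pileup[rt.start : rt.start + cfg.read_length] += 1
        means.append(pileup.mean())
    assert np.mean(means) == pytest.approx(25.0, rel=0.05)


def test_depth_must_be_positive_for_reads():
    _, haps, truth = simulate_haplotypes(CLEAN)
    bad = replace(CLEAN, depth=-5.0)
    with pytest.raises(ValueError, match="depth"):
        simulate_reads(truth, haps, bad)


# ---------------------------------------------------------------------------
# PAF emission


def test_carrier_cigar_contains_insertion_and_noncarrier_is_match_only():
    cfg = replace(CLEAN, sv_unit_length=2_300, backbone_length=30_000, sv_breakpoint=15_000)
    _, haps, _ = simulate_haplotypes(cfg)
    records = {r.qname: r for r in emit_paf(haps, cfg.backbone_length)}
    for hap in haps:
        rec = records[hap.name]
        rec.validate()
        if hap.carrier:
            assert "6900I" in rec.tags["cg"]
        else:
            assert rec.tags["cg"] == "30000M"
            assert rec.matches == rec.block_len == 30_000


def test_paf_round_trip_preserves_coordinates(small_cohort):
    lines = [format_paf(r) for r in small_cohort.paf]
    back = parse_paf(lines)
    assert back == small_cohort.paf


def test_snp_mismatches_reduce_residue_matches():
    cfg = replace(CLEAN, snp_rate=0.01)
    _, haps, _ = simulate_haplotypes(cfg)
    records = {r.qname: r for r in emit_paf(haps, cfg.backbone_length)}
    snpy = [h for h in haps if not h.carrier and any(":" in sid for sid, _ in h.composition)]
    assert snpy, "with snp_rate=0.01 some haplotype should carry SNPs"
    for hap in snpy:
        n_alt = sum(1 for sid, _ in hap.composition if ":" in sid)
        assert records[hap.name].matches == cfg.backbone_length - n_alt
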