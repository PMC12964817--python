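"""Interval projection checked against a base-by-base aligned-pair oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panloc.intervals import GenomicInterval
from panloc.paf import PafRecord, cigar_query_span, cigar_target_span
from panloc.projection import project_interval

# ---------------------------------------------------------------------------
# independent oracle: enumerate aligned (target, query) base pairs


def aligned_pairs(rec):
    t = rec.tstart
    q = rec.qstart if rec.strand == "+" else rec.qend
    pairs = []
    for n, op in rec.cigar:
        if op in "M=X":
            for i in range(n):
                pairs.append((t + i, q + i if rec.strand == "+" else q - 1 - i))
            t += n
            q = q + n if rec.strand == "+" else q - n
        elif op == "I":
            q = q + n if rec.strand == "+" else q - n
        elif op in "DN":
            t += n
    return pairs


def oracle_image(rec, t0, t1):
    qs = [q for t, q in aligned_pairs(rec) if t0 <= t < t1]
    if not qs:
        return None
    return min(qs), max(qs) + 1


def make_record(cigar_ops, strand="+", tstart=0, qstart=0, qname="ctg", tname="ref"):
    cg = "".join(f"{n}{op}" for n, op in cigar_ops)
    qspan = cigar_query_span(cigar_ops)
    tspan = cigar_target_span(cigar_ops)
    rec = PafRecord(
        qname=qname,
        qlen=qstart + qspan + 10,
        qstart=qstart,
        qend=qstart + qspan,
        strand=strand,
        tname=tname,
        tlen=tstart + tspan + 10,
        tstart=tstart,
        tend=tstart + tspan,
        matches=sum(n for n, op in cigar_ops if op in "M=X"),
        block_len=sum(n for n, _ in cigar_ops),
        mapq=60,
        tags={"cg": cg},
    )
    rec.validate()
    return rec


# ---------------------------------------------------------------------------


def test_match_only_identity_offset():
    rec = make_record([(1000, "M")], tstart=1000, qstart=0)
    (seg,) = project_interval([rec], GenomicInterval("ref", 1100, 1200))
    assert (seg.image.start, seg.image.end) == (100, 200)
    assert (seg.source.start, seg.source.end) == (1100, 1200)
    assert not seg.approximate


def test_deletion_spanning_window_matches_oracle():
    # 100 bp missing from the query in the middle of the alignment
    rec = make_record([(500, "M"), (100, "D"), (500, "M")], tstart=1000, qstart=0)
    target = GenomicInterval("ref", 1400, 1700)
    (seg,) = project_interval([rec], target)
    assert (seg.image.start, seg.image.end) == oracle_image(rec, 1400, 1700)
    assert (seg.image.start, seg.image.end) == (400, 600)


def test_reverse_strand_full_span_gives_full_query():
    rec = make_record([(800, "M")], strand="-", tstart=500, qstart=30)
    (seg,) = project_interval([rec], GenomicInterval("ref", 0, 10_000))
    assert (seg.image.start, seg.image.end) == (rec.qstart, rec.qend)
    assert seg.image.strand == "-"


def test_window_inside_deletion_yields_no_segment():
    rec = make_record([(100, "M"), (300, "D"), (100, "M")])
    assert project_interval([rec], GenomicInterval("ref", 150, 350)) == []


def test_non_overlapping_and_other_chromosome_skipped():
    rec = make_record([(100, "M")], tstart=0)
    assert project_interval([rec], GenomicInterval("ref", 500, 600)) == []
    assert project_interval([rec], GenomicInterval("chrX", 0, 50)) == []


def test_without_cigar_interpolates_and_flags_approximate():
    rec = make_record([(1000, "M")], tstart=1000)
    rec.tags.pop("cg")
    (seg,) = project_interval([rec], GenomicInterval("ref", 1250, 1750))
    assert seg.approximate
    assert (seg.image.start, seg.image.end) == (250, 750)


def test_round_trip_on_match_only_alignment():
    """Projecting ref->query then the image query->ref recovers the source."""
    rec = make_record([(1000, "M")], tstart=2000, qstart=500)
    target = GenomicInterval("ref", 2100, 2400)
    (seg,) = project_interval([rec], target)
    inverse = PafRecord(
        qname="ref",
        qlen=rec.tlen,
        qstart=rec.tstart,
        qend=rec.tend,
        strand="+",
        tname="ctg",
        tlen=rec.qlen,
        tstart=rec.qstart,
        tend=rec.qend,
        matches=rec.matches,
        block_len=rec.block_len,
        mapq=60,
        tags={"cg": "1000M"},
    )
    (back,) = project_interval(
        [inverse], GenomicInterval("ctg", seg.image.start, seg.image.end)
    )
    assert (back.image.start, back.image.end) == (target.start, target.end)


# ---------------------------------------------------------------------------
# property: random CIGARs agree with the aligned-pair enumeration

_ops = st.lists(
    st.tuples(st.integers(1, 40), st.sampled_from("MIDMM")),  # M-rich mix
    min_size=1,
    max_size=12,
).map(lambda ops: [(5, "M")] + ops + [(5, "M")])


@settings(derandomize=True, max_examples=300, deadline=None)
@given(
    ops=_ops,
    strand=st.sampled_from("+-"),
    tstart=st.integers(0, 50),
    qstart=st.integers(0, 50),
    data=st.data(),
)
def test_projection_agrees_with_aligned_pair_oracle(ops, strand, tstart, qstart, data):
    rec = make_record(ops, strand=strand, tstart=tstart, qstart=qstart)
    t0 = data.draw(st.integers(rec.tstart - 5, rec.tend + 5))
    t1 = data.draw(st.integers(t0, rec.tend + 10))
    segs = project_interval([rec], GenomicInterval("ref", max(t0, 0), max(t1, 0)))
    expected = oracle_image(rec, max(t0, 0), max(t1, 0))
    if expected is None:
        assert segs == []
    else:
        (seg,) = segs
        assert (seg.image.start, seg.image.end) == expected


# ---------------------------------------------------------------------------
# sequence extraction of projected images


def test_extract_full_contig_identity():
    from panloc.projection import ProjectedSegment, extract_region_sequences

    seqs = {"ctg": "ACGTACGTGG"}
    rec = make_record([(10, "M")], qname="ctg")
    seg = ProjectedSegment(
        source=GenomicInterval("ref", 0, 10),
        image=GenomicInterval("ctg", 0, 10, "+"),
        identity=1.0,
        via=rec,
    )
    ((header, seq),) = extract_region_sequences(seqs, [seg])
    assert seq == seqs["ctg"]
    assert header == "ctg:0-10:+"


def test_extract_reverse_strand_is_reverse_complement():
    from panloc._util import revcomp
    from panloc.projection import ProjectedSegment, extract_region_sequences

    seqs = {"ctg": "ACGTACGTGGTT"}
    rec = make_record([(8, "M")], qname="ctg")
    fwd = ProjectedSegment(GenomicInterval("ref", 0, 8), GenomicInterval("ctg", 2, 10, "+"), 1.0, rec)
    rev = ProjectedSegment(GenomicInterval("ref", 0, 8), GenomicInterval("ctg", 2, 10, "-"), 1.0, rec)
    ((_, s_fwd),) = extract_region_sequences(seqs, [fwd])
    ((_, s_rev),) = extract_region_sequences(seqs, [rev])
    assert s_rev == revcomp(s_fwd)
    assert revcomp(s_rev) == s_fwd  # involution


def test_extract_out_of_bounds_or_unknown_contig_is_an_error():
    import pytest as _pytest

    from panloc.projection import ProjectedSegment, extract_region_sequences

    rec = make_record([(10, "M")], qname="ctg")
    seg = ProjectedSegment(GenomicInterval("ref", 0, 10), GenomicInterval("ctg", 5, 15, "+"), 1.0, rec)
    with _pytest.raises(ValueError, match="past contig end"):
        extract_region_sequences({"ctg": "ACGTACGTGG"}, [seg])
    with _pytest.raises(ValueError, match="absent"):
        extract_region_sequences({}, [seg])


def test_extract_composes_with_projection():
    """Extracting a projected window returns the reference window's sequence
    when the contig is an exact copy of that reference region."""
    from panloc.projection import extract_region_sequences

    ref = "ACGTTGCAACGGTTAACCGGTTAA" * 10
    contig = ref[40:200]  # exact match-only alignment ref[40,200) <-> ctg[0,160)
    rec = make_record([(160, "M")], tstart=40, qname="ctg")
    target = GenomicInterval("ref", 100, 150)
    (seg,) = project_interval([rec], target)
    ((_, seq),) = extract_region_sequences({"ctg": contig}, [seg])
    assert seq == ref[100:150]
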