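# Methods

This note documents the models and procedures `panloc` implements, the
parameters that matter, what the synthetic cohorts do and do not emulate, and
the design choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The analysis in one paragraph

A structural variant (SV) at a known locus is studied through a *local*
pangenome: a reference interval is projected onto assembly contigs through
their alignments (PAF); the admitted sequences form a variation graph (GFA)
in which each assembly is a path; nodes are classified by how many samples
traverse them; a run of *variable* nodes shared by one exact subset of
samples is a candidate SV allele; short-read samples are then genotyped by
the depth of their graph alignments (GAF) over those nodes; finally carrier
status is tested for association with a binary phenotype.

## Coordinates and formats

All internal coordinates are 0-based half-open (PAF/BED convention).
Command-line region strings are samtools-style 1-based inclusive and
converted exactly once at the boundary (`parse_region`). PAF, GFA (1.0
S/L/P, with GFA 1.1 W walks converted to the same in-memory paths) and GAF
are parsed by the package itself; records that parse but violate coordinate
or CIGAR-consistency invariants are rejected *individually* with a reason,
so one bad record never discards a file.

## Interval projection

For each alignment overlapping the target interval, the image on the contig
is the span of query bases aligned to reference bases inside the clipped
window, found by walking the CIGAR (`M/=/X` advance both sequences, `I` the
query, `D/N` the reference; on `'-'` strand records the query cursor runs
backwards from `qend`, per the PAF convention). A window falling entirely in
a deletion has no image. Records without a CIGAR are projected by
proportional interpolation across the alignment block and the segment is
flagged `approximate`, so base-exact and interpolated coordinates are never
confused. Correctness is checked against an independent oracle that
enumerates aligned base pairs one by one.

### Contig admission

"Additional" contigs (sequences recovered from outside the target
chromosome interval) are admitted when their aligned length is at least
`min_len` (default 10,000 bp) **and** covers at least `min_frac` (default
0.80) of the whole contig. Aligned length is the length of the *union* of
image intervals — overlapping projections are not double-counted; the union
is the conservative reading of an aligned "size". Every decision is
reported, and a contig failing only the coverage-fraction rule is annotated,
because published tables contain at least one such borderline contig and
silent disagreement would be invisible. The filters apply to additional
sequences only; the primary target-chromosome projections are exempt.

### Translocation signatures

A contig touching the target interval is summarized as its ordered list of
reference blocks (chromosome, interval, strand) in contig coordinate order,
with blocks shorter than `min_block` (default 5,000 bp on the contig)
suppressed as alignment noise. Two flags are derived: *multi-chromosome*
(blocks on more than one chromosome) and *non-colinear* (same-chromosome
blocks whose reference order, given their strands, does not follow their
contig order — e.g. a downstream segment repositioned upstream, the
signature of the serial chromosome 6 ↔ 29 translocation at this locus).
Mixed strands within a chromosome are conservatively flagged non-colinear.

## Path depth and node classes

Sample identity is the path-name prefix before a delimiter (default `'#'`,
PanSN style), so the two haplotype paths of one sample — or the single path
of a pseudo-haploid assembly — count once. For each node the package keeps
both the traversal *multiplicity* per path (cycles count every traversal;
this carries the copy-number signal of tandem repeats) and the *depth* =
number of distinct samples. Classes follow pangenome convention: depth = n
core, depth = 1 private, otherwise variable. Which of the two counts "path
coverage" should mean is ambiguous in general, so both are always computed;
depth drives classification, multiplicity drives copy-number estimates.

## Differential subregions

Published analyses of this kind located the SV by visual inspection of a
colored graph layout; reproducibility requires an algorithm instead. The
one implemented groups variable nodes by their exact carrier-sample set,
orders them along a designated backbone path (off-backbone nodes inherit
the position of their nearest backbone neighbor by BFS, so non-DAG graphs
are handled), splits groups where more than `max_gap` (default 5) backbone
positions intervene, and reports runs with at least `min_carriers`
(default 2) carriers and a minimum size (default 1,000 bp). Ties in the
length-descending output order are broken by backbone position, for
determinism.

Each call reports two sizes. `node_length` is the summed length of the
member nodes. When an allele is a tandem repeat collapsed onto shared
nodes, carrier paths traverse those nodes several times, and the *inserted*
sequence length is the node length scaled by the per-allele traversal
multiplicity (median across carriers): `inserted_length`. The distinction
matters: a 3 × 2.3 kb insertion is one 2,300 bp node traversed three times,
but the allele inserts 6,900 bp of sequence. Size filtering and ranking use
`inserted_length`.

The backbone is whichever path the caller designates; the pipeline picks
the first non-carrier haplotype (falling back to the first path). Any
backbone gives the same grouping; it only anchors ordering and gap
measurement.

## Coverage genotyping

Per-node coverage is gafpack-style base counting: each record's aligned
span `[path_start, path_end)` is intersected with the node intervals along
its walk, so assigned bases per record equal the span exactly (an invariant
the tests verify record by record) and soft-clipped portions never count.
A best-alignment filter keeps one record per read (highest residue matches,
then mapping quality, then lexicographically smallest path), reproducing a
max-multimap-1 alignment policy downstream of any aligner. Traversal
counting (one unit per overlapped step) is available as an option.

Normalization is "over both sequencing depth and length of the region":
raw per-base coverage over the node set divided by the sample's sequencing
depth. The depth denominator is deliberately region-local — the median
per-base coverage over *core* nodes of the analyzed graph — because core
nodes are genotype-independent and the median resists repeat-inflated
nodes; a known genome-wide depth can be supplied as an override. Genotype
bands on the allele-dosage statistic (normalized coverage divided by
`copies_per_allele`, the per-allele unit multiplicity taken from the
subregion call) are half-open with boundaries in the upper class:
dosage < 0.25 absent, < 0.75 het, < 1.5 hom, ≥ 1.5 dup. The 0.25/0.75
boundaries sit symmetrically between the expected 0 / 0.5 / 1.0 states and
1.5 is the upper edge of the diploid band; all are configurable, since any
thresholding of a continuous statistic is a choice. The copy-number
estimate `round(2 × normalized)` (half-even) counts SV units across the
diploid genome and is reported alongside the categorical call.

## Association

The carrier-by-phenotype 2×2 table is tested with a two-sided Fisher exact
test under the minimum-likelihood rule: sum the probabilities of all tables
on the observed margins whose point probability does not exceed the
observed one, with probabilities within 1e-7 relative counted as ties. The
hypergeometric numerators are built by an exact integer recurrence and the
tie comparison is done in integers, so the p-value is identical on every
platform. The odds ratio applies the Haldane–Anscombe +0.5 correction only
when a cell is zero, and says so. Dominance concordance is the fraction of
samples where carrying at least one copy coincides with the dominant
phenotype, with discordant samples listed. Units are assemblies/samples —
each counts once.

## The synthetic cohorts

The generator emulates the statistical structure the analysis relies on,
with defaults chosen as the study conditions: a 30,000 bp backbone; an
insertion of `sv_copies` = 3 identical units of `sv_unit_length` = 2,300 bp
(≈ 7 kb) at its midpoint; 40 diploid samples (12 carriers, het/hom with
probability ½ each, one carrier haplotype carrying in hets); 150 bp
single-end reads at 30× per sample; substitution errors at 0.001/bp;
private substitution SNPs at 0.0005/bp per haplotype. Modelling choices and
what they imply:

- **Identical repeat units, shared nodes.** Copy number manifests as
  repeated traversals and hence elevated coverage on shared SV nodes — the
  duplicated-sequence interpretation of elevated short-read coverage. The
  units carry no internal variation.
- **SNPs are substitutions on the backbone only** (no indels, none inside
  SV units), keeping truth-GAF coordinates exact and the copy-number signal
  clean. Each SNP splits the backbone at a global segmentation shared by
  all haplotypes, so one truth graph holds every sample.
- **Reads are single-end and uniform** with Poisson read counts per
  haplotype at depth/2; paired-end geometry, GC bias, mapping ambiguity and
  alignment error add nothing to the coverage statistic under test and are
  not modelled. Truth GAF records are exact sub-walks of the haplotype
  path; substitution errors reduce residue matches but never move a read.
- **Dominance is built in**: phenotype is white iff genotype ≠ absent, so a
  perfect method should reach concordance 1.0 — deviations measure the
  method, not biology.
- **Determinism**: one seed drives everything; per-sample and per-read
  randomness uses sub-streams keyed by (seed, stream index), so adding
  samples never perturbs earlier ones, and identical configs produce
  byte-identical FASTA/GFA/PAF/GAF output. Truth GAF uses forward steps
  only; reverse-orientation handling is exercised by hand-built fixtures in
  the coverage tests.
- The translocation simulator builds a two-chromosome toy reference and a
  contig with the downstream target-chromosome segment repositioned
  upstream of a second-chromosome insertion point, plus a colinear control.

Consequently, passing tests show that the *method* recovers what its
assumptions describe; they do not show robustness to divergent repeat
copies, indel-rich regions, alignment artifacts or reference bias, which
real data contain. Zygosity in real pseudo-haploid (e.g. CLR) assemblies is
a further caveat: one path per sample can only show presence, not genotype.

## Problem sizes and numerical choices

Validation experiments run at the study conditions above: genotype recovery
aggregates ten 40-sample cohorts at 30× (400 genotypes); subregion recovery
uses twenty graph-only replicates; the projection oracle checks 1,000
random CIGARs; the Fisher implementation is compared with exhaustive
enumeration for every 2×2 table with total ≤ 60. Unit tests reuse a
smaller cohort (6 kb backbone, 3 × 400 bp insertion, 10 samples at 20×),
where per-sample depth estimates fluctuate by a few percent (Poisson noise
at ~1,200 reads), so those tests assert 10 % per sample and 5 % on the
cohort mean. Degenerate inputs error loudly rather than guess: empty node
sets, empty cohorts, zero estimated depth, all-zero contingency tables,
depth exceeding the sample count.

## Known limitations

- Proportional interpolation (CIGAR-less PAF) is approximate near indels;
  such segments are flagged but still used by admission filtering.
- Subregion detection requires carriers to share the *exact* carrier set on
  every member node; genotyping errors upstream (in real graphs, spurious
  private nodes) fragment calls rather than merging them.
- The depth estimator assumes the analyzed graph contains enough core
  sequence; for a graph consisting mostly of the SV itself, supply the
  genome-wide depth override.
- Copy-number resolution above ~6 units is limited by `round(2ĉ)` on a
  noisy statistic; the categorical `dup` call is robust, the integer less so.
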