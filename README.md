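# panloc — local-pangenome analysis of a structural variant

`panloc` is a toolkit for studying one structural variant (SV) at one locus
with a *local* pangenome, the strategy used to characterize the multi-kilobase
tandem insertion upstream of the bovine *KIT* gene that segregates with the
white-headed phenotype in cattle. Instead of building a whole-genome graph, the
workflow projects a single reference interval onto many assemblies, builds a
variation graph of just that region, and reads SV genotypes for short-read
samples directly off the graph. It is written for geneticists who have
assembly-vs-reference alignments (PAF), a local variation graph (GFA) and
read-to-graph alignments (GAF), and who want reproducible, scriptable answers
rather than a graph viewer.

The pieces, usable separately or as one pipeline:

- **Interval projection** (`panloc.projection`): parse PAF, lift a reference
  interval `[s, e)` onto each contig by CIGAR walk (exact) or proportional
  interpolation (flagged), admit "additional" contigs under the two filters —
  aligned length ≥ 10 kb AND alignment covering ≥ 80 % of the contig — and
  scan contigs for translocation signatures (multi-chromosome or non-colinear
  block orders, the hallmark of the serial chromosome 6 ↔ 29 *KIT*
  translocations behind color-sidedness).
- **Variation graph** (`panloc.graph`): GFA 1.0/1.1 in, per-node *path depth*
  (distinct samples traversing a node; PanSN-style `sample#hap` path names),
  node classes — **core** (depth = n), **private** (depth = 1), **variable**
  (in between) — and detection of *differential subregions*: runs of variable
  nodes sharing one exact carrier-sample set, i.e. candidate SV alleles.
- **Coverage genotyping** (`panloc.coverage`): GAF in, per-node aligned-base
  accumulation, normalized region coverage
  `ĉ = (Σ bases / Σ node lengths) / depth` so that a diploid region sits at
  1.0, a heterozygous allele at 0.5, and duplicated sequence above 1.5; calls
  `absent / het / hom / dup` with copy number `round(2ĉ)`.
- **Association** (`panloc.association`): per-breed carrier tables, an exact
  two-sided Fisher test computed by full hypergeometric enumeration in integer
  arithmetic, and a dominance-concordance check (carrier ⇔ white-headed).
- **Synthetic truth** (`panloc.simulate`): cohorts with a known insertion of
  repeated units, dominant phenotype map, uniform reads with truth GAF, PAF
  with the insertion in the CIGAR, and a translocation-bearing contig — the
  oracle every other module is validated against.

## Worked example

Run the bundled demo — a simulated cohort of 40 diploid samples (12 carriers,
28 non-carriers) at 30× over a 30 kb locus with a 3 × 2,300 bp insertion:

```bash
cat > demo.yaml <<'YAML'
outdir: panloc_demo
simulate:
  seed: 1
YAML
panloc run --config demo.yaml
```

The run writes `sim/`, `projection/`, `graph/`, `genotypes/`, `association/`
and `summary.json` under `panloc_demo/`. With seed 1 the truth graph has 3,642
nodes (2,396 core, 1,234 private, 12 variable); the one differential-subregion
call covers the SV-unit node (2,300 bp, traversed 3× per carrier allele, i.e.
an inserted length of 6,900 bp) with exactly the 12 truth carriers. The
genotype table begins

```
sample  n_reads  depth_estimate  normalized  dosage  call  copy_number
S000    7334     29.0            3.1556      1.0519  hom   6
S001    6760     30.0            1.5300      0.5100  het   3
```

— `normalized` is region coverage over depth (a het carrier of a 3-copy
insertion sits near 1.5), `dosage` divides by the allele's copy number so the
0 / 0.5 / 1.0 genotype bands apply, and `copy_number = round(2 × normalized)`
counts SV units across the diploid genome. The association report ends with

```
Fisher exact two-sided p = 1.790e-10
Dominance concordance = 1.0000 (0 discordant: none)
Genotype concordance with simulation truth = 1.0000
```

i.e. all 12 white-headed samples and none of the 28 colored-headed samples
carry the allele (`[[12, 0], [0, 28]]`), every called genotype matches truth,
and carrier status coincides perfectly with the dominant phenotype.

The same subcommands work on real files: `panloc project --paf aln.paf
--region 6:69000000-71000000`, `panloc classify --gfa graph.gfa`,
`panloc detect-sv`, `panloc genotype`, `panloc associate`.

## Layout

```
src/panloc/        intervals, paf, projection, graph, gaf, coverage,
                   association, simulate, experiments, pipeline, cli, datasets
tests/             pytest suite (unit, property and acceptance tests)
scripts/           acceptance.py
docs/methods.md    models, parameters, design choices, limitations
```
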