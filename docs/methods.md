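# Methods

## Model and assumptions

`linediff` treats pooled-library sequencing of two inbred-ish lines as a
direct read-count experiment.  Each line is one pool of `pool_size` diploid
individuals (default 10), so a site's reads are draws from 2N haplotypes
and the fraction of reads supporting an alternate event estimates that
line's alternate-allele frequency.  The pipeline's statistic, the SNP rate,
is exactly this fraction taken for the *most frequent* non-reference event
(substitution base, deletion, or insertion) over the total base-supporting
depth.  Ties between events break by the fixed order A < C < G < T < del <
ins, purely for determinism.

Assumptions this makes, and where they bite:

- **Equal representation of birds in the pool.**  Unequal DNA input skews
  the frequency estimate; nothing in the counts can detect it.
- **No mapping bias or base-quality model.**  Filtering is by pooled allele
  fractions and depth only.  This is deliberate: the target is near-fixed
  line differences, which survive crude filters, not low-frequency alleles.
- **One variant per site, at most two alleles.**  The caller reports the
  top non-reference event only; true multi-allelic sites lose information.

### Counts representation

`SiteCounts` stores per-site A/C/G/T/deletion read counts with the
invariant `depth = A + C + G + T + del`.  Insertion anchors (reference
`'-'`) follow the gapped-assembly convention of the source tables: reads
carrying the inserted base may sit in that base's column (then `del` counts
reads agreeing with the reference gap and the depth invariant holds
unchanged), or arrive via the counts TSV's `ins` column, in which case
`depth = ins + del`.  Both forms normalise to `count_ins`/`ins_seq`.

## Calling and the dual-call rule

A site is called when the top event has at least `min_count` = 2 reads and
unrounded rate at least `min_rate` = 0.05 — the permissive assembly-level
thresholds; rounding to two decimals is display-only, so a 9/12 = 0.75 site
passes a 0.75 cutoff on exact arithmetic.

The upstream caller the design replaces was a proprietary diploid-Bayesian
one, so duality (reference retained, rendered `REF|ALT`) is re-derived by a
transparent rule: **dual iff the reference-supporting fraction strictly
exceeds 0.20** (`dual_ref_frac`, configurable).  This threshold reproduces
every single-versus-dual assignment in the packaged 156-row marker table
(reference fractions 2/10 = 0.20 stay single; 3/14 ≈ 0.21 and up go dual).
Duality applies to substitutions; indel calls render as `-` or the inserted
sequence regardless.  Note the printed table orders dual alleles
inconsistently (`C|A` but also `T|C` for a C reference); the package always
renders reference first, and fixture comparisons therefore compare the
allele *set* plus the dual flag.

## The differential cascade

Stage order: subtraction → rate ≥ 0.75 → amino-acid-changing → depth ≥ 10 →
recount.  Each stage logs (name, in, out).

- **Subtraction** defaults to the `position_allele` key: a site variant in
  both lines with *different* alleles is still line-informative.  A
  `position` key is provided because "occurring in both lines" is ambiguous
  at the position level.
- **Recount confirmation** replaces a manual alignment-viewer re-scan with
  the strictest automated reading: recomputed depth ≥ 10, recomputed rate
  of the *called* allele ≥ 0.75, and that allele still the top event; drops
  record a reason (`no-data`/`depth`/`rate`/`allele`).  Reproducibility was
  preferred over fidelity to an undocumented manual step.
- Summaries tally unique calls per chromosome (via a configurable
  contig→chromosome map; the packaged one covers the galGal accessions the
  fixture tables use), per region class (CDS > UTR > intron > intergenic
  precedence when transcripts overlap), and per impact class.

## Consequence annotation

c. coordinates count spliced CDS bases from the initiator A; all c. bases
are reported in CDS-strand orientation (genomic alleles on minus-strand
genes are reverse-complemented), which is standard HGVS practice even
though a few printed rows mix conventions.  Impact classes:

- `no_start`: any change away from ATG at codon 1 (takes precedence),
- `nonsense`: sense codon → stop (stop rendered `.` in the table dialect,
  `*` available),
- `synonymous` / `non_synonymous` by translated residue,
- `frameshift`: CDS indel with length not divisible by 3, named
  `<refAA><codon>fs` at the first codon whose translation changes.  One
  printed row (`c.388C > -` as `Y129fs`) names the codon *before* the
  shift; the package emits codon 130 and the fixture-consistency test
  records that row as the single known exception rather than matching it.

With multiple transcripts per gene the longest CDS is canonical
(`canonical_models`), overridable by passing a model subset.  Variants
spanning a CDS boundary classify by their first CDS-overlapping base.
Two naming dialects exist: `standard` (`c.368C>T`, `c.388del`,
`c.105insA`) and `paper` (`c.368C > T`, `c.388C > -`, `c.105- > A`),
byte-compatible with the printed tables up to an extraction artifact that
inserts a space before `T` reference bases.

## Validation panels

Panel observations are per-bird Sanger-style calls (one or two base
symbols, or an insertion-presence flag).  Heterozygotes contribute 0.5 to
each allele, so per-line tallies sum to bird counts; ratio strings reduce
by GCD after doubling away the halves.  Insertion markers render
`Ins_<seq>_<pct>%` where the percentage is the *fraction of birds carrying
the insertion* — the printed table does not say whether its percentages are
bird- or allele-level, and the bird-level reading was chosen and is noted
here.  The `differential` flag (alternate-frequency difference > 0.25
between lines) and the optional Fisher exact test are additions of this
package: the original design reported ratios qualitatively.

## Simulator

`SimConfig` defaults define the emulated study: 2 contigs × 100 kb at GC
0.42, 20 genes (1–4 exons, 60–200 codons, ATG…stop, no internal stop, both
strands), pools of 10 diploid birds, Poisson(6) depth per site matching the
5–7× coverage band of the emulated libraries, miscall rate 0.005, and 200
planted variants: 80 shared at frequency 0.5, 80 case-only and 40
control-only fixed at frequency 1.0, half coding, 10% indels.  Planted
coding substitutions are resampled until amino-acid-changing, since the
cascade's target class is protein-altering variants; their truth impact
comes from an inline genetic-code table independent of the annotator.
Genotypes are Binomial(2, f) per bird; reads pick a bird uniformly, then
one of its haplotypes.

What the simulator does **not** model: read-level errors correlated along
reads, mapping bias, indel sequencing error, paired-end geometry, unequal
pooling, linkage between variants.  Passing recovery tests therefore show
the cascade's logic is correct under the pool-binomial model, not that the
thresholds are optimal on real libraries.

Counts are simulated only at planted positions.  Variant-free positions
cannot produce calls without errors and would only add runtime; the
consequence is that false positives can arise only at planted sites (e.g.
shared variants leaking through subtraction), which is exactly what the
precision metric is meant to catch.

## Recovery evaluation

`evaluate_recovery` scores reported markers against *eligible* truth:
case-only, amino-acid-changing planted variants whose simulated case
counts meet the design thresholds (depth ≥ 10 and true-allele support
fraction ≥ 0.75).  Conditioning the denominator on the realised counts
separates the cascade's correctness from Poisson coverage censoring: a
variant the library never covered ten-deep is not a recall failure of the
pipeline.  Precision counts all reported markers.  The impact confusion
table compares truth labels with annotated labels on the true positives and
is diagonal on noiseless runs.

## Numerical and policy choices

- All thresholds compare unrounded floats; two-decimal values are display.
- Coordinates are 1-based closed intervals internally; VCF emission uses
  the standard anchor-base convention for indels (deletion at P reported at
  P−1; insertion after P anchored at P), and dual calls become one record
  with FILTER `DUAL` — the reference allele is retained, so a second ALT
  would misstate the genotype.
- Sizes in tests and the acceptance script (default simulator scale, 3
  seeds for oracle sweeps, 10⁴ random instances for property checks) keep
  the whole suite in a few seconds while exceeding the property-test counts
  the package commits to.
- Degenerate inputs: depth-0 sites are an error for `snp_rate` and a
  no-call for `call_site`; empty marker tables load as an empty list with a
  warning; CDS lengths not divisible by 3 load with `length_warning` set.
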