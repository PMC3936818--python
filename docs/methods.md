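# Methods

## The data model

`patchlift` operates on variant catalogues of homozygous-inbred varieties
called against a single reference genome. The exchange format is SDI: a
tab-separated table with five mandatory columns — chromosome, 1-based
position, length change δ = len(alt) − len(ref), reference allele,
variant allele — with `-` for the empty allele and extra columns carried
through opaquely. Positions point at the first affected reference base;
a pure insertion is anchored *after* its position (position 0 inserts
before base 1), which keeps the δ bookkeeping additive. Records are
assumed to be one consensus call per site: two records touching the same
reference base (an insertion also claims its two flanking bases) are
rejected rather than merged, because nothing in a consensus file says
which call should win.

Four variant classes cover every record: SNPs (1 bp → 1 bp), insertions
(empty reference allele), deletions (empty variant allele), and
*unbalanced insertions* — replacements whose variant allele is longer
than their reference allele. Length-decreasing replacements are tallied
with deletions (net sequence loss), and equal-length multi-base
substitutions are decomposed into per-base SNPs at read time, so
class-level accounting always partitions the catalogue exactly. A variant
allele containing an IUPAC ambiguity code (R, Y, S, W, K, M, B, D, H, V)
marks an ambiguous call — in an inbred line these are putative
heterozygous sites or mapping artefacts — and every report counts them
both included and excluded. `N` is treated as a plain (unambiguous)
symbol.

## Reconstruction and coordinate translation

Applying a variant set to a chromosome is a single left-to-right splice;
the length of the result must equal the reference length plus Σδ, and
this is asserted on every run. The same pass produces the offset map: a
piecewise-constant function from reference to variety coordinates with
breakpoints at each indel, plus the list of removed reference intervals.
Lifting a position p adds the cumulative δ of all edits ending before p;
a position inside a removed interval either reports as deleted or clamps
to the last surviving base before the interval, at the caller's choice.
A replacement maps its matched prefix min(len(ref), len(alt)) one-to-one
and treats any remaining reference bases as removed.

Annotation liftover applies this map to every GFF3 feature endpoint.
Feature starts inside a removed interval clamp *forward* to the first
surviving base, ends clamp *backward*; a feature left with no surviving
bases is dropped and its parents are flagged truncated. Clamping (rather
than dropping) features that merely overlap a deletion endpoint is the
default because it keeps gene models liftable; every such event is
recorded in the lift report. CDS phases are recomputed from the lifted
CDS lengths in coding order rather than copied, so a transcript that lost
sequence stays internally consistent. Coordinates are 1-based inclusive
throughout (GFF3 convention); only the chain-file export uses 0-based
half-open intervals and says so in its header. The chain round trip
preserves lifting semantics exactly but represents a length-increasing
replacement as deletion-plus-insertion at the same breakpoint — a
distinction lifting cannot observe.

The apply→extract round trip (re-deriving the variant set from the
reference, the reconstructed genome and the map) is the identity whenever
consecutive records are separated by at least one unedited base, and is
used as the reconstruction verifier. Applying the same variant set twice
fails loudly: after one application, every SNP downstream of an indel
sits at a shifted coordinate and no longer matches its reference allele.

## Effect classification

Context is assigned per overlapped gene with precedence CDS > splice site
> UTR > intron > flank > intergenic. The splice-site window is the first
and last 2 bases of each intron — the canonical GT/AG dinucleotides, and
the narrowest defensible reading of "splice-site mutation". The
upstream/downstream flank is 5,000 bp by default (the conventional
default of SnpEff-style effect predictors), configurable.

Coding SNVs are classified by codon arithmetic on the coding strand:
mutate the affected codon, translate both versions with the standard
code, and compare — synonymous, missense (emitting `<refAA><pos><altAA>`,
e.g. `T82A`), start_lost (codon 1 no longer ATG), stop_gained, or
stop_lost. CDS indels are frameshift iff δ mod 3 ≠ 0, else in-frame.
The test suite checks every codon-arithmetic call against an independent
oracle that translates the *entire* mutant CDS and diffs the proteins.
Ambiguous-allele SNVs keep their context but receive no effect call; they
are reported separately, never silently mixed into coding statistics.

Transfer status per gene follows a strict precedence: any disrupting
effect (frameshift, start/stop alteration) ⇒ not transferred; else any
splice-site disruption ⇒ transferred with altered structure; else
transferred. The mapping is monotone — adding damage can never improve a
gene's status — and genes untouched by any variant are transferred.

Protein-impact scores are an *input*: a gene/variant/score TSV
(PROVEAN-style, more negative = more damaging) thresholded at the
conventional −2.5. Score computation is out of scope.

## Summary statistics

All printed percentages use half-up rounding to one decimal. Expected
sequencing depth is 2·pairs·read-length/genome-size. Shared/specific
partitions use exact (chrom, pos, ref, alt) identity. "Polymorphic
regions" are approximated by merging variant footprints separated by at
most 100 bp (a read-coverage definition needs reads, which this package
never consumes); the N50 of the complementary monomorphic stretches uses
the standard definition — the segment length L such that segments ≥ L
cover at least half the summed length. A gene counts as polymorphic when
any variant falls within its span, UTRs and introns included.

## Enrichment

Each GO term with at least one study hit is tested by the upper-tail
hypergeometric probability P[X ≥ k] for X ~ Hypergeom(N, K, n), computed
via `scipy.stats.hypergeom.sf`. Correction is Benjamini–Hochberg step-up
by default; because "Hochberg (FDR)" is ambiguous — FDR is the property
BH controls, while Hochberg's 1988 step-up controls FWER — the Hochberg
procedure is also available behind `method="hochberg"`. Both are
cross-checked against `statsmodels.stats.multitest.multipletests`. Study
lists smaller than 20 genes are gated out (small classes give the test no
power), the number of tested terms after the min-mapping gate is the
correction's m, and GO-graph ancestor propagation is off by default
(enable only when the annotation is known to be leaf-only). Note that BH
adjusted p-values are *not* idempotent under re-application (the m/rank
multiplier applies again); the invariants that do hold — adjusted ≥ raw,
capped at 1, order preserving — are the ones tested.

## The synthetic-data generator

The generator emulates the *shape* of a two-variety resequencing study:

* a random background genome (default 2 × 150 kb, GC 0.36 — a plant-like
  AT-rich composition) carrying 60 canonical genes: ATG start, single
  terminal stop, no internal stops, CDS length ≡ 0 mod 3, GT..AG introns,
  UTRs, both strands;
* background SNPs at 2×10⁻³/bp and indels at 4×10⁻⁴/bp (rates high
  enough to exercise every code path on a desk-scale genome; real
  genome-wide rates are an order of magnitude lower);
* SNPs mostly variety-specific (shared fraction 0.02) while indels are
  majority-shared (0.65), mirroring the empirical observation that common
  indels largely reflect reference errors rather than true variation;
* 3.3% of SNPs ambiguous, with IUPAC two-base codes;
* indel lengths from a geometric 1–5 bp body with a rare (1%) 100–5,000 bp
  log-uniform tail, capped at 5 kb insertions / 36 kb deletions;
* exact quotas of engineered coding effects (default: 4 synonymous,
  4 missense, 3 frameshift, 2 start_lost, 2 stop_gained,
  3 splice_disrupted), one per gene, placed deterministically at sites
  that guarantee the intended effect and verified internally by
  translating the full mutant CDS.

Every variant carries a truth record (class, context, effect, owning
gene, variety membership), with background CDS effects labelled by the
translation-diff oracle — a different route from the classifier's codon
arithmetic. Identical seeds give byte-identical bundles; each generation
stage draws from its own seed-derived stream.

The `paper-shaped` preset scales to 400 genes on 2 × 650 kb, assigns them
to six named fruit-quality/regulatory classes (three of them ≥ 20 members
and therefore enrichment-eligible), and writes a score table of 386
scored genes of which exactly 45 fall at or below the −2.5 cutoff.

What the generator does **not** emulate: repeats and mappability (the
dominant source of real ambiguous calls), read-level coverage, linkage
between nearby variants, realistic gene density, or GO term correlation
structure. Green tests therefore demonstrate the correctness of the
bookkeeping, coordinate arithmetic and statistics — not the behaviour of
upstream read mapping or variant calling on real data.

## Problem sizes and numerical choices

The default test bundle is 300 kb/60 genes (~850 variants); round-trip
and recovery statistics use a 3 Mb/~11,300-variant bundle — sizes chosen
so the full suite runs in well under a minute while keeping binomial
standard errors small enough for 3·SE recovery checks at the configured
rates. Oracle-equivalence tests run the coordinate lifter against a
per-base origin-tracking map on 1,000 random genomes (checking every edit
boundary ±1 plus random interior positions — boundaries are where
off-by-one errors live), the hypergeometric tail against exact rational
combinatorics for all configurations with N ≤ 25 at 12 significant
digits, and N50 against a direct cumulative-sum implementation.
Enrichment calibration uses 500 null draws (any-enrichment rate ≤
α + 3·SE) and 100 seeded draws of a constructed enriched fixture
(detected in all 100).

Degenerate inputs are defined, not improvised: empty variant sets yield
identity reconstructions and all-zero tables; a validation-concordance
denominator of zero reports NA; an empty enrichment study (or one below
the class-size gate) returns an empty result; zero-length alleles on both
sides of a record are invalid.
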