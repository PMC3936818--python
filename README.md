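# patchlift

Variant-aware genome reconstruction and annotation liftover for
homozygous-inbred crop varieties.

When a variety of a crop such as tomato is resequenced against a reference
genome, the result is usually not a new assembly but a *variant catalogue*:
SNPs, insertions and deletions relative to the reference, distributed as
plain-text SDI files (chrom, position, length change, reference allele,
variant allele). `patchlift` turns such a catalogue back into sequence and
biology:

* **Reconstruct** variety pseudomolecules by applying the variant set to
  the reference FASTA, chromosome by chromosome.
* **Lift** the reference gene annotation (GFF3) onto the reconstructed
  genome: every coordinate is shifted by the cumulative length change
  Δ(p) = Σ<sub>indels upstream of p</sub> δ of the indels before it;
  features falling inside deleted intervals are dropped or clamped and
  reported.
* **Classify** each variant by genomic context (CDS > splice site > UTR >
  intron > 5 kb flank > intergenic) and, in coding sequence, by effect:
  synonymous, missense (with an amino-acid-change string such as `T82A`),
  start/stop alterations, frameshift (indel with δ mod 3 ≠ 0), in-frame
  indel, or splice-site disruption (first/last 2 intron bases, the GT/AG
  dinucleotides).
* **Assign transfer statuses**: a gene hit by a disrupting mutation
  (frameshift, start/stop alteration) is *not transferred* to the variety
  annotation; splice-site damage alone yields *transferred with altered
  structure*; everything else transfers intact.
* **Summarise**: variant class tables with ambiguous (IUPAC
  heterozygous-like) calls counted both included and excluded, per-feature
  breakdowns stratified by indel length, shared-versus-specific partitions
  between two varieties, expected sequencing depth (2·pairs·L/G), the N50
  of monomorphic stretches between variant clusters, and per-gene-class
  polymorphism tables.
* **Enrich**: singular enrichment analysis of variant-bearing gene sets by
  the upper-tail hypergeometric test, P[X ≥ k] with
  X ~ Hypergeom(N, K, n), under Benjamini–Hochberg FDR correction.

A synthetic-data generator (`patchlift.simulate`) produces reference
genomes with canonical gene models, paired variety variant sets with
ground-truth labels, score tables and GO annotations, so that every stage
is testable offline. External protein-impact scores (PROVEAN-style) are
consumed as an input table and thresholded at the conventional −2.5; they
are never computed here.

## Worked example

```python
from patchlift import (SimConfig, simulate, apply_variants, classify_effects,
                       transfer_statuses)
from patchlift.stats import variant_class_counts, shared_specific, transfer_summary

b = simulate(SimConfig(seed=11))            # 2 x 150 kb, 60 genes, 2 varieties
print(variant_class_counts(b.variants_a))
```

```
                      count  count_excluding_ambiguous
SNP                     343                        334
deletion                 25                         25
insertion               54                         54
unbalanced_insertion    11                         11
Total                   433                        424
```

Variety A carries 433 variants, of which 9 SNPs are ambiguous
(IUPAC codes, putative heterozygous calls) — the second column excludes
them, mirroring the parenthesised counts of a variant-statistics table.

```python
common, a_only, b_only = shared_specific(b.variants_a, b.variants_b)
print(len(common), len(a_only), len(b_only))      # 93 340 319

variety, offset_map = apply_variants(b.reference, b.variants_a)
print(variety.total_length() - b.reference.total_length())   # +92 bp net

calls = classify_effects(b.variants_a, b.models, b.reference)
print(transfer_summary(transfer_statuses(calls, b.models), 60))
```

```
                   count  percent
transferred           52     86.7
altered_structure      2      3.3
not_transferred        6     10.0
```

Six genes carry disrupting mutations (frameshifts or start/stop
alterations) and would not be transferred to the variety annotation; two
have splice-site damage only.

The same pipeline runs from the shell:

```bash
patchlift simulate --preset default --seed 11 --out bundle/
patchlift reconstruct --ref bundle/reference.fasta --sdi bundle/variety_A.sdi \
    --out-fasta A.fasta --out-chain A.chain
patchlift lift --gff bundle/annotation.gff3 --chain A.chain \
    --out A.gff3 --report A_lift.tsv
```

or end to end from a YAML config with `patchlift run --config run.yaml`
(see `patchlift.pipeline.CONFIG_SCHEMA`).

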