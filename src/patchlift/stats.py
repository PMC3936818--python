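"""Variant accounting and genome-level summary statistics.

Reimplements the bookkeeping a variety-resequencing study reports: variant
counts by class with ambiguous calls counted both included and excluded,
per-feature breakdowns stratified by indel length, shared-versus-specific
partitions between two varieties, the expected sequencing depth
arithmetic, the N50 of monomorphic stretches between clustered variants,
gene transfer percentages, SNP validation concordance against independent
evidence, and per-gene-class polymorphism tables.

All printed percentages are rounded half-up to one decimal.
"""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .effects import EffectCall, TransferStatus
from .errors import ValidationError
from .sdi_io import (
    VariantRecord,
    VariantClass,
    classify_variant,
    group_by_chrom,
    is_ambiguous,
)

#: Order of the class rows in variant accounting tables.
CLASS_ORDER = [
    VariantClass.SNP,
    VariantClass.DELETION,
    VariantClass.INSERTION,
    VariantClass.UNBALANCED_INSERTION,
]

#: Feature rows of the per-context tables.  Near-gene and intergenic
#: variants share a row; splice sites are intron bases.
FEATURE_ORDER = ["intergenic", "intronic", "UTR", "CDS"]

_CONTEXT_TO_FEATURE = {
    "intergenic": "intergenic",
    "upstream": "intergenic",
    "downstream": "intergenic",
    "intronic": "intronic",
    "splice_site": "intronic",
    "UTR": "UTR",
    "CDS": "CDS",
}

_FEATURE_PRECEDENCE = {"CDS": 0, "UTR": 1, "intronic": 2, "intergenic": 3}


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (2.25 -> 2.3), as used for all printed
    percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def with_total_row(df: pd.DataFrame, label: str = "Total") -> pd.DataFrame:
    """Append a totals row summing every numeric column."""
    total = df.sum(numeric_only=True)
    total.name = label
    return pd.concat([df, total.to_frame().T])


# -- variant class accounting ------------------------------------------------


def variant_class_counts(records: Iterable[VariantRecord]) -> pd.DataFrame:
    """Counts per variant class, with and without ambiguous calls,
    plus a Total row."""
    counts = {c: 0 for c in CLASS_ORDER}
    counts_excl = {c: 0 for c in CLASS_ORDER}
    for rec in records:
        cls = classify_variant(rec)
        counts[cls] += 1
        if not is_ambiguous(rec):
            counts_excl[cls] += 1
    df = pd.DataFrame(
        {
            "count": [counts[c] for c in CLASS_ORDER],
            "count_excluding_ambiguous": [counts_excl[c] for c in CLASS_ORDER],
        },
        index=[c.value for c in CLASS_ORDER],
    )
    return with_total_row(df)


# -- per-feature breakdown ---------------------------------------------------


def _indel_length(variant: VariantRecord) -> int:
    return abs(variant.delta)


def feature_breakdown(
    calls: Iterable[EffectCall],
    strata: Mapping[str, tuple[int | None, int | None]] | None = None,
) -> pd.DataFrame:
    """Variant and distinct-gene counts per feature, per length stratum.

    Each variant is counted in exactly one feature row — its
    highest-precedence context across the genes it overlaps (CDS > UTR >
    intronic > intergenic, with splice sites tallied as intronic and
    near-gene flanks as intergenic) — so feature counts sum to the number
    of distinct variants.  ``strata`` maps stratum label to an inclusive
    (min, max) bound on the indel length |delta| (None = unbounded); the
    default reproduces the conventional total / shorter-than-6 /
    longer-than-100 rows.
    """
    if strata is None:
        strata = {"total": (None, None), "lt6": (None, 5), "gt100": (101, None)}
    per_variant: dict[tuple, dict] = {}
    for call in calls:
        key = call.variant.key
        entry = per_variant.setdefault(
            key, {"variant": call.variant, "feature": "intergenic", "genes": set()}
        )
        feature = _CONTEXT_TO_FEATURE[call.context]
        if _FEATURE_PRECEDENCE[feature] < _FEATURE_PRECEDENCE[entry["feature"]]:
            entry["feature"] = feature
        if call.gene_id is not None:
            entry["genes"].add((feature, call.gene_id))

    rows = []
    for label, (lo, hi) in strata.items():
        counts = {f: 0 for f in FEATURE_ORDER}
        genes: dict[str, set] = {f: set() for f in FEATURE_ORDER}
        for entry in per_variant.values():
            length = _indel_length(entry["variant"])
            if lo is not None and length < lo:
                continue
            if hi is not None and length > hi:
                continue
            feature = entry["feature"]
            counts[feature] += 1
            for gf, gid in entry["genes"]:
                if gf == feature:
                    genes[feature].add(gid)
        for feature in FEATURE_ORDER:
            rows.append(
                {
                    "stratum": label,
                    "feature": feature,
                    "variants": counts[feature],
                    "genes": len(genes[feature]),
                }
            )
    return pd.DataFrame(rows)


# -- shared vs specific ------------------------------------------------------


def shared_specific(
    records_a: Iterable[VariantRecord], records_b: Iterable[VariantRecord]
) -> tuple[list[VariantRecord], list[VariantRecord], list[VariantRecord]]:
    """Partition two varieties' sets into (common, A-only, B-only) by
    exact (chrom, pos, ref, alt) identity."""
    a = list(records_a)
    b = list(records_b)
    keys_b = {r.key for r in b}
    keys_a = {r.key for r in a}
    common = [r for r in a if r.key in keys_b]
    a_only = [r for r in a if r.key not in keys_b]
    b_only = [r for r in b if r.key not in keys_a]
    return common, a_only, b_only


def shared_fraction(common_count: int, variety_count: int) -> float:
    """Percent of a variety's variants shared with the other genotype,
    half-up rounded to one decimal."""
    if variety_count == 0:
        raise ValidationError("variety_count must be positive")
    return round_half_up(100.0 * common_count / variety_count, 1)


# -- depth arithmetic --------------------------------------------------------


def expected_depth(
    read_pairs: int, read_length: int, genome_size: int
) -> float:
    """Expected fold coverage from paired-end counts: 2*pairs*length/size,
    one decimal."""
    if genome_size <= 0:
        raise ValidationError("genome_size must be positive")
    if read_pairs <= 0 or read_length <= 0:
        raise ValidationError("read_pairs and read_length must be positive")
    return round_half_up(2.0 * read_pairs * read_length / genome_size, 1)


# -- polymorphic regions and N50 ---------------------------------------------


def polymorphic_regions(
    records: Iterable[VariantRecord], merge_gap: int = 100
) -> dict[str, list[tuple[int, int]]]:
    """Per chromosome, variant footprints merged when separated by at most
    ``merge_gap`` unaffected bases — a variant-cluster proxy for the
    complex polymorphic regions a read-coverage analysis would flag."""
    if merge_gap < 0:
        raise ValidationError("merge_gap must be >= 0")
    regions: dict[str, list[tuple[int, int]]] = {}
    for chrom, recs in group_by_chrom(records).items():
        merged: list[list[int]] = []
        for rec in recs:
            s, e = rec.footprint()
            if merged and s - merged[-1][1] - 1 <= merge_gap:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        regions[chrom] = [(s, e) for s, e in merged]
    return regions


def complement_segments(
    regions: Mapping[str, list[tuple[int, int]]],
    chrom_lengths: Mapping[str, int],
) -> list[int]:
    """Lengths of the contiguous stretches between polymorphic regions,
    over all chromosomes."""
    lengths: list[int] = []
    for chrom, total in chrom_lengths.items():
        cursor = 1
        for s, e in regions.get(chrom, []):
            if s > cursor:
                lengths.append(min(s - 1, total) - cursor + 1)
            cursor = max(cursor, e + 1)
        if cursor <= total:
            lengths.append(total - cursor + 1)
    return lengths


def n50(segment_lengths: Sequence[int]) -> int:
    """Standard N50: the length L such that segments of length >= L cover
    at least half the summed length."""
    lengths = sorted((int(x) for x in segment_lengths), reverse=True)
    if not lengths:
        return 0
    half = sum(lengths) / 2.0
    cum = 0
    for length in lengths:
        cum += length
        if cum >= half:
            return length
    return lengths[-1]  # pragma: no cover


def n50_between(
    records: Iterable[VariantRecord],
    chrom_lengths: Mapping[str, int],
    merge_gap: int = 100,
) -> int:
    """N50 of the monomorphic stretches between merged variant clusters."""
    regions = polymorphic_regions(records, merge_gap)
    return n50(complement_segments(regions, chrom_lengths))


# -- transfer summary --------------------------------------------------------


def transfer_summary(
    statuses: Mapping[str, TransferStatus], total_annotations: int
) -> pd.DataFrame:
    """Counts and percentages of each transfer status over the full
    annotation; genes not in ``statuses`` count as transferred intact."""
    n_not = sum(1 for s in statuses.values() if s is TransferStatus.NOT_TRANSFERRED)
    n_alt = sum(1 for s in statuses.values() if s is TransferStatus.ALTERED_STRUCTURE)
    if total_annotations < n_not + n_alt:
        raise ValidationError(
            "total_annotations smaller than the number of damaged genes"
        )
    n_ok = total_annotations - n_not - n_alt
    rows = {
        TransferStatus.TRANSFERRED.value: n_ok,
        TransferStatus.ALTERED_STRUCTURE.value: n_alt,
        TransferStatus.NOT_TRANSFERRED.value: n_not,
    }
    return pd.DataFrame(
        {
            "count": list(rows.values()),
            "percent": [
                round_half_up(100.0 * v / total_annotations, 1)
                for v in rows.values()
            ],
        },
        index=list(rows.keys()),
    )


# -- validation concordance --------------------------------------------------


def validation_concordance(
    genomic_snps: Iterable[VariantRecord],
    evidence: pd.DataFrame,
    min_depth: int = 6,
) -> float | None:
    """Fraction of genomic SNPs confirmed by independent evidence calls.

    ``evidence`` needs columns chrom, pos, alt, depth (e.g. RNA-seq SNP
    calls).  Only genomic SNP sites with evidence depth >= ``min_depth``
    enter the denominator; returns None when no site qualifies.
    """
    ev = {}
    for row in evidence.itertuples(index=False):
        ev[(row.chrom, int(row.pos))] = (str(row.alt), int(row.depth))
    n_covered = 0
    n_match = 0
    for rec in genomic_snps:
        hit = ev.get((rec.chrom, rec.pos))
        if hit is None or hit[1] < min_depth:
            continue
        n_covered += 1
        if hit[0] == rec.alt_allele:
            n_match += 1
    if n_covered == 0:
        return None
    return n_match / n_covered


# -- gene-class polymorphism tables ------------------------------------------

_IN_SPAN_CONTEXTS = {"CDS", "splice_site", "UTR", "intronic"}


def gene_class_table(
    classes: Mapping[str, Sequence[str]],
    calls_by_variety: Mapping[str, Iterable[EffectCall]],
    annotated_genes: set[str],
) -> pd.DataFrame:
    """Per-gene-class polymorphism report across two (or more) varieties.

    A gene is polymorphic in a variety when at least one variant falls
    anywhere in its span (CDS, UTR, intron or splice site).  The output
    has one row per class plus a Total row with, per variety, the
    polymorphic gene count, its percentage of the class, and the variant
    count; plus the cross-variety common/specific gene partition.
    Class members absent from the annotation are warned about and
    excluded.
    """
    varieties = list(calls_by_variety)
    poly_genes: dict[str, set[str]] = {}
    var_counts: dict[str, dict[str, int]] = {}
    for variety, calls in calls_by_variety.items():
        genes: set[str] = set()
        counts: dict[str, int] = {}
        for call in calls:
            if call.gene_id is None or call.context not in _IN_SPAN_CONTEXTS:
                continue
            genes.add(call.gene_id)
            counts[call.gene_id] = counts.get(call.gene_id, 0) + 1
        poly_genes[variety] = genes
        var_counts[variety] = counts

    rows = []
    for cls_name, members in classes.items():
        members = list(dict.fromkeys(members))
        known = [g for g in members if g in annotated_genes]
        missing = set(members) - set(known)
        if missing:
            warnings.warn(
                f"gene class {cls_name!r}: {len(missing)} member(s) absent "
                "from the annotation were excluded"
            )
        row: dict = {"gene_class": cls_name, "genes": len(known)}
        poly_by_variety = {}
        for variety in varieties:
            poly = [g for g in known if g in poly_genes[variety]]
            poly_by_variety[variety] = set(poly)
            row[f"{variety}_polymorphic"] = len(poly)
            row[f"{variety}_polymorphic_pct"] = (
                round_half_up(100.0 * len(poly) / len(known), 1) if known else 0.0
            )
            row[f"{variety}_variants"] = sum(
                var_counts[variety].get(g, 0) for g in known
            )
        if len(varieties) == 2:
            a, b = varieties
            common = poly_by_variety[a] & poly_by_variety[b]
            row["common"] = len(common)
            row[f"{a}_specific"] = len(poly_by_variety[a] - common)
            row[f"{b}_specific"] = len(poly_by_variety[b] - common)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("gene_class")
    pct_cols = [c for c in df.columns if c.endswith("_pct")]
    totals = df.drop(columns=pct_cols).sum(numeric_only=True)
    totals.name = "Total"
    df = pd.concat([df, totals.to_frame().T])
    return df
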