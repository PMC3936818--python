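"""Genomic-context and coding-effect classification of variants.

Each variant is first placed in a genomic context relative to the gene
models it overlaps — with precedence CDS > splice site > UTR > intronic >
upstream/downstream (within a configurable window, default 5 kb) >
intergenic — and, for coding contexts, assigned an effect by codon
arithmetic on the coding strand:

* SNVs: synonymous, missense (with an amino-acid-change string such as
  ``T82A``), start_lost, stop_lost, or stop_gained;
* indels: frameshift when the length change is not a multiple of three,
  otherwise inframe_indel;
* anything touching the first or last two bases of an intron (the
  canonical GT/AG dinucleotides): splice_disrupted.

Variant-allele ambiguity codes mark putative heterozygous calls in an
inbred line; such SNVs keep their context but are excluded from coding
effect calls and reported separately.

From the per-gene effect calls a transfer status is assigned: a gene hit
by a disrupting mutation (frameshift or start/stop alteration) is not
transferred to the variety annotation; a gene with only splice-site damage
is transferred with putative altered structure; everything else transfers
intact.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .errors import PatchliftError, ValidationError
from .genome import Genome
from .gff import GeneModel
from .sdi_io import VariantRecord, is_ambiguous

#: Default near-gene window (bp) for upstream/downstream assignment.
DEFAULT_WINDOW = 5000

#: Default splice-site half-window: first/last bases of each intron.
SPLICE_WIDTH = 2

#: Conventional deleterious cutoff for protein-variant impact scores.
PROVEAN_CUTOFF = -2.5

CONTEXTS = (
    "intergenic",
    "upstream",
    "downstream",
    "intronic",
    "UTR",
    "CDS",
    "splice_site",
)

EFFECTS = (
    "none",
    "synonymous",
    "missense",
    "start_lost",
    "stop_lost",
    "stop_gained",
    "frameshift",
    "inframe_indel",
    "splice_disrupted",
)

DISRUPTING_EFFECTS = {"frameshift", "start_lost", "stop_lost", "stop_gained"}


class TransferStatus(enum.Enum):
    TRANSFERRED = "transferred"
    ALTERED_STRUCTURE = "altered_structure"
    NOT_TRANSFERRED = "not_transferred"


@dataclass(frozen=True)
class EffectCall:
    variant: VariantRecord
    gene_id: str | None
    context: str
    effect: str = "none"
    aa_change: str | None = None
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValidationError(f"unknown context {self.context!r}")
        if self.effect not in EFFECTS:
            raise ValidationError(f"unknown effect {self.effect!r}")
        if self.effect != "none" and self.context not in ("CDS", "splice_site"):
            raise ValidationError(
                f"effect {self.effect!r} outside a coding context"
            )


class GeneIndex:
    """Interval index over gene spans expanded by the near-gene window."""

    def __init__(self, models: Sequence[GeneModel], window: int = DEFAULT_WINDOW):
        self.window = window
        self.models = {m.gene_id: m for m in models}
        self._trees: dict[str, IntervalTree] = {}
        for m in models:
            tree = self._trees.setdefault(m.chrom, IntervalTree())
            # half-open 0-based for intervaltree
            tree.addi(max(0, m.start - window - 1), m.end + window, m.gene_id)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(start - 1, end)
        return sorted(
            (self.models[h.data] for h in hits), key=lambda m: (m.start, m.gene_id)
        )


def _footprint(variant: VariantRecord) -> tuple[int, int]:
    if variant.ref_allele:
        return variant.pos, variant.pos + len(variant.ref_allele) - 1
    return variant.pos, variant.pos + 1


def _overlaps(fp: tuple[int, int], intervals: Iterable[tuple[int, int]]) -> bool:
    return any(fp[0] <= e and s <= fp[1] for s, e in intervals)


def assign_context(
    variant: VariantRecord,
    index: GeneIndex,
) -> list[tuple[str, str | None]]:
    """Contexts of a variant, one ``(context, gene_id)`` pair per
    overlapped gene; ``[("intergenic", None)]`` when it touches none."""
    fp = _footprint(variant)
    calls: list[tuple[str, str | None]] = []
    for model in index.overlapping(variant.chrom, fp[0], fp[1]):
        if _overlaps(fp, model.cds):
            calls.append(("CDS", model.gene_id))
        elif _overlaps(fp, model.splice_windows(SPLICE_WIDTH)):
            calls.append(("splice_site", model.gene_id))
        elif _overlaps(fp, model.utrs):
            calls.append(("UTR", model.gene_id))
        elif fp[0] <= model.end and model.start <= fp[1]:
            calls.append(("intronic", model.gene_id))
        else:
            before = fp[1] < model.start
            if model.strand == "+":
                side = "upstream" if before else "downstream"
            else:
                side = "downstream" if before else "upstream"
            calls.append((side, model.gene_id))
    if not calls:
        calls.append(("intergenic", None))
    return calls


def cds_effect(
    variant: VariantRecord,
    gene: GeneModel,
    reference: Genome,
    context: str = "CDS",
) -> EffectCall:
    """Coding effect of a variant already placed in CDS or splice_site."""
    if context not in ("CDS", "splice_site"):
        raise PatchliftError(
            f"cds_effect called with non-coding context {context!r}"
        )
    if context == "splice_site":
        return EffectCall(variant, gene.gene_id, context, "splice_disrupted")
    if variant.delta != 0:
        effect = "frameshift" if variant.delta % 3 != 0 else "inframe_indel"
        return EffectCall(variant, gene.gene_id, context, effect)

    # SNV: codon arithmetic on the coding strand
    local = gene.cds_local_position(variant.pos)
    if local is None:
        raise PatchliftError(
            f"{variant.chrom}:{variant.pos} outside CDS of {gene.gene_id}"
        )
    cds_seq = gene.cds_sequence(reference)
    codon_idx = (local - 1) // 3
    within = (local - 1) % 3
    ref_codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
    alt_base = variant.alt_allele
    if gene.strand == "-":
        alt_base = str(Seq(alt_base).reverse_complement())
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())

    if codon_idx == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        return EffectCall(variant, gene.gene_id, context, "start_lost")
    if ref_aa == "*" and alt_aa != "*":
        return EffectCall(variant, gene.gene_id, context, "stop_lost")
    if alt_aa == "*" and ref_aa != "*":
        return EffectCall(variant, gene.gene_id, context, "stop_gained")
    if ref_aa == alt_aa:
        return EffectCall(variant, gene.gene_id, context, "synonymous")
    return EffectCall(
        variant,
        gene.gene_id,
        context,
        "missense",
        aa_change=f"{ref_aa}{codon_idx + 1}{alt_aa}",
    )


def classify_effects(
    variants: Iterable[VariantRecord],
    models: Sequence[GeneModel],
    reference: Genome,
    window: int = DEFAULT_WINDOW,
) -> list[EffectCall]:
    """Context + effect call for every variant, one call per overlapped
    gene.  Ambiguous-allele SNVs keep context but get effect ``none``."""
    index = GeneIndex(models, window)
    calls: list[EffectCall] = []
    for variant in variants:
        ambiguous = is_ambiguous(variant)
        for context, gene_id in assign_context(variant, index):
            if context in ("CDS", "splice_site") and not ambiguous:
                call = cds_effect(
                    variant, index.models[gene_id], reference, context
                )
            else:
                call = EffectCall(
                    variant, gene_id, context, "none", ambiguous=ambiguous
                )
            calls.append(call)
    return calls


def transfer_status(calls: Iterable[EffectCall]) -> TransferStatus:
    """Transfer status of one gene from all of its effect calls.

    Disruption dominates altered structure, which dominates intact
    transfer; a gene with no coding damage (including an untouched gene)
    is TRANSFERRED.
    """
    effects = {c.effect for c in calls}
    if effects & DISRUPTING_EFFECTS:
        return TransferStatus.NOT_TRANSFERRED
    if "splice_disrupted" in effects:
        return TransferStatus.ALTERED_STRUCTURE
    return TransferStatus.TRANSFERRED


def transfer_statuses(
    calls: Iterable[EffectCall], models: Sequence[GeneModel]
) -> dict[str, TransferStatus]:
    """One status per gene; genes without calls are TRANSFERRED."""
    by_gene: dict[str, list[EffectCall]] = {m.gene_id: [] for m in models}
    for call in calls:
        if call.gene_id is not None and call.gene_id in by_gene:
            by_gene[call.gene_id].append(call)
    return {gid: transfer_status(gcalls) for gid, gcalls in by_gene.items()}


# -- external deleterious scores --------------------------------------------


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read a gene/variant/score TSV of externally computed protein-impact
    scores (PROVEAN-style; more negative = more damaging)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene": str})
    required = {"gene", "variant", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"score table missing columns {sorted(missing)}")
    if not pd.api.types.is_numeric_dtype(df["score"]):
        try:
            df["score"] = df["score"].astype(float)
        except ValueError as exc:
            raise ValidationError(f"non-numeric score: {exc}")
    return df


def call_deleterious(
    scores: pd.DataFrame, threshold: float = PROVEAN_CUTOFF
) -> tuple[pd.DataFrame, dict]:
    """Flag variants with score <= threshold and summarise per gene.

    Returns the table with a ``deleterious`` column plus a summary dict
    with the count and fraction of genes carrying at least one deleterious
    variant.
    """
    out = scores.copy()
    out["deleterious"] = out["score"] <= threshold
    per_gene = out.groupby("gene")["deleterious"].any()
    n_genes = int(per_gene.size)
    n_deleterious = int(per_gene.sum())
    summary = {
        "n_genes": n_genes,
        "n_deleterious_genes": n_deleterious,
        "fraction": n_deleterious / n_genes if n_genes else float("nan"),
    }
    return out, summary


def effect_table(calls: Iterable[EffectCall]) -> pd.DataFrame:
    """Flat per-call table (variant key, gene, context, effect, aa change)."""
    rows = []
    for c in calls:
        v = c.variant
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref_allele or "-",
                "alt": v.alt_allele or "-",
                "gene": c.gene_id or "",
                "context": c.context,
                "effect": c.effect,
                "aa_change": c.aa_change or "",
                "ambiguous": c.ambiguous,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene",
            "context", "effect", "aa_change", "ambiguous",
        ],
    )
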