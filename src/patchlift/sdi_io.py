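"""Reading, writing and classifying SDI variant records.

The SDI ("SNPs, Deletions, Insertions") format is a per-variety tab-separated
table of differences against a reference genome, one record per line::

    chrom <TAB> pos <TAB> delta <TAB> ref_allele <TAB> alt_allele [extra...]

* ``pos`` is 1-based.  For records with a non-empty reference allele it is
  the first affected reference base; for pure insertions it is the reference
  base *after which* the inserted sequence is placed (``pos == 0`` inserts
  before the first base).
* ``delta`` is ``len(alt) - len(ref)``; a ``-`` denotes the empty allele.
* Lines starting with ``#`` are comments.  Columns beyond the fifth are
  preserved opaquely on round trip.

Records fall into exactly four classes: SNPs, insertions, deletions, and
"unbalanced insertions" — length-increasing replacements where both alleles
are non-empty.  Length-*decreasing* replacements are tallied with deletions,
and equal-length multi-base substitutions are decomposed into per-base SNPs
at read time, so downstream accounting only ever sees the four classes.

A variant allele containing an IUPAC ambiguity code (R, Y, S, W, K, M, B,
D, H, V) marks an ambiguous call — in a homozygous inbred line these are
putative heterozygous sites or mapping artefacts, and reports count them
both included and excluded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import (
    IntegrityError,
    ReferenceMismatchError,
    SdiParseError,
    ValidationError,
)
from .genome import Genome

#: Codes whose presence in the variant allele marks an ambiguous call.
AMBIGUITY_CODES = frozenset("RYSWKMBDHV")

_ALLELE_ALPHABET = frozenset("ACGTN")
_ALT_ALPHABET = _ALLELE_ALPHABET | AMBIGUITY_CODES


class VariantClass(enum.Enum):
    SNP = "SNP"
    INSERTION = "insertion"
    DELETION = "deletion"
    UNBALANCED_INSERTION = "unbalanced_insertion"


@dataclass(frozen=True, order=True)
class VariantRecord:
    """One SDI record.

    ``ref_allele``/``alt_allele`` are plain strings; the empty string is the
    empty allele (written ``-`` on disk).  ``extra`` carries any trailing
    columns verbatim.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    extra: tuple[str, ...] = field(default_factory=tuple, compare=False)

    def __post_init__(self) -> None:
        if not self.ref_allele and not self.alt_allele:
            raise ValidationError(
                f"{self.chrom}:{self.pos}: both alleles empty"
            )
        if self.ref_allele:
            if self.pos < 1:
                raise ValidationError(
                    f"{self.chrom}:{self.pos}: pos must be >= 1 for a "
                    "record with a reference allele"
                )
            bad = set(self.ref_allele) - _ALLELE_ALPHABET
            if bad:
                raise ValidationError(
                    f"{self.chrom}:{self.pos}: invalid reference allele "
                    f"characters {sorted(bad)}"
                )
        elif self.pos < 0:
            raise ValidationError(
                f"{self.chrom}:{self.pos}: pos must be >= 0 for an insertion"
            )
        bad = set(self.alt_allele) - _ALT_ALPHABET
        if bad:
            raise ValidationError(
                f"{self.chrom}:{self.pos}: invalid variant allele "
                f"characters {sorted(bad)}"
            )

    @property
    def delta(self) -> int:
        """Net length change introduced by this record."""
        return len(self.alt_allele) - len(self.ref_allele)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity used when intersecting variant sets across varieties."""
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    def footprint(self) -> tuple[int, int]:
        """Inclusive 1-based reference interval this record occupies.

        Pure insertions occupy no reference base; their footprint is the
        two flanking bases ``(pos, pos+1)`` so that adjacency conflicts
        (another edit touching the same junction) are detected.
        """
        if self.ref_allele:
            return (self.pos, self.pos + len(self.ref_allele) - 1)
        return (self.pos, self.pos + 1)


def classify_variant(record: VariantRecord) -> VariantClass:
    """Map a record to one of the four variant classes (total, deterministic)."""
    ref, alt = record.ref_allele, record.alt_allele
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNP
    if not ref:
        return VariantClass.INSERTION
    if not alt:
        return VariantClass.DELETION
    if len(alt) > len(ref):
        return VariantClass.UNBALANCED_INSERTION
    if len(alt) < len(ref):
        # length-decreasing replacement: net loss, tallied with deletions
        return VariantClass.DELETION
    raise ValidationError(
        f"{record.chrom}:{record.pos}: equal-length multi-base substitution "
        "must be decomposed into SNPs before classification"
    )


def is_ambiguous(record: VariantRecord) -> bool:
    """True iff the variant allele contains an IUPAC ambiguity code."""
    return bool(set(record.alt_allele) & AMBIGUITY_CODES)


def sort_records(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    return sorted(records, key=lambda r: (r.chrom, r.pos, r.ref_allele, r.alt_allele))


def group_by_chrom(records: Iterable[VariantRecord]) -> dict[str, list[VariantRecord]]:
    """Group records by chromosome, sorted by position within each."""
    grouped: dict[str, list[VariantRecord]] = {}
    for rec in sort_records(records):
        grouped.setdefault(rec.chrom, []).append(rec)
    return grouped


def check_no_overlap(records: Iterable[VariantRecord]) -> None:
    """Raise :class:`ValidationError` if two records touch the same base.

    Records are compared through :meth:`VariantRecord.footprint`, so a pure
    insertion conflicts with any edit touching either flanking base — the
    pipeline emits one consensus call per site and never merges.
    """
    for chrom, recs in group_by_chrom(records).items():
        prev = None
        for rec in recs:
            if prev is not None:
                if rec.footprint()[0] <= prev.footprint()[1]:
                    raise ValidationError(
                        f"overlapping records on {chrom}: "
                        f"{prev.pos}:{prev.ref_allele or '-'}>"
                        f"{prev.alt_allele or '-'} and "
                        f"{rec.pos}:{rec.ref_allele or '-'}>"
                        f"{rec.alt_allele or '-'}"
                    )
            prev = rec


def _decompose_substitution(
    chrom: str, pos: int, ref: str, alt: str, extra: tuple[str, ...]
) -> list[VariantRecord]:
    """Split an equal-length multi-base substitution into per-base SNPs,
    dropping positions where the two alleles agree."""
    out = []
    for i, (r, a) in enumerate(zip(ref, alt)):
        if r != a:
            out.append(VariantRecord(chrom, pos + i, r, a, extra))
    return out


def read_sdi(path: str | Path) -> list[VariantRecord]:
    """Parse an SDI file into records sorted by (chrom, pos).

    The file's delta column is re-derived from the alleles and checked;
    a disagreement raises :class:`IntegrityError`.  Overlapping records
    raise :class:`ValidationError`.
    """
    records: list[VariantRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise SdiParseError(
                    f"expected >=5 tab-separated columns, got {len(fields)}",
                    lineno,
                )
            chrom, pos_s, delta_s, ref, alt = fields[:5]
            extra = tuple(fields[5:])
            try:
                pos = int(pos_s)
                delta_file = int(delta_s)
            except ValueError as exc:
                raise SdiParseError(f"non-integer pos/delta: {exc}", lineno)
            ref = "" if ref == "-" else ref.upper()
            alt = "" if alt == "-" else alt.upper()
            try:
                if len(ref) == len(alt) and len(ref) > 1:
                    new = _decompose_substitution(chrom, pos, ref, alt, extra)
                else:
                    new = [VariantRecord(chrom, pos, ref, alt, extra)]
            except ValidationError as exc:
                raise SdiParseError(str(exc), lineno)
            derived_delta = len(alt) - len(ref)
            if derived_delta != delta_file:
                raise IntegrityError(
                    f"line {lineno}: delta column {delta_file} disagrees "
                    f"with alleles (len(alt)-len(ref) = {derived_delta})"
                )
            records.extend(new)
    records = sort_records(records)
    check_no_overlap(records)
    return records


def write_sdi(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records as an SDI file (sorted; byte-stable round trip)."""
    records = sort_records(records)
    check_no_overlap(records)
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tdelta\tref\talt\n")
        for rec in records:
            cols = [
                rec.chrom,
                str(rec.pos),
                str(rec.delta),
                rec.ref_allele or "-",
                rec.alt_allele or "-",
                *rec.extra,
            ]
            fh.write("\t".join(cols) + "\n")


def to_vcf(
    records: Iterable[VariantRecord], reference: Genome, path: str | Path
) -> None:
    """Export records as VCF 4.2, left-anchoring indels on the preceding base.

    Raises :class:`ReferenceMismatchError` when a record's reference allele
    disagrees with the reference sequence.
    """
    records = sort_records(records)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in reference:
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in records:
            chrom = rec.chrom
            if chrom not in reference:
                raise ReferenceMismatchError(f"unknown chromosome {chrom!r}")
            if rec.ref_allele:
                observed = reference.fetch(
                    chrom, rec.pos, rec.pos + len(rec.ref_allele) - 1
                )
                if observed != rec.ref_allele:
                    raise ReferenceMismatchError(
                        f"{chrom}:{rec.pos}: SDI ref {rec.ref_allele!r} != "
                        f"reference sequence {observed!r}"
                    )
            if len(rec.ref_allele) == 1 and len(rec.alt_allele) == 1:
                pos, ref, alt = rec.pos, rec.ref_allele, rec.alt_allele
            elif not rec.ref_allele:
                if rec.pos >= 1:
                    anchor = reference.fetch(chrom, rec.pos, rec.pos)
                    pos, ref, alt = rec.pos, anchor, anchor + rec.alt_allele
                else:
                    # insertion before base 1: anchor on the following base
                    anchor = reference.fetch(chrom, 1, 1)
                    pos, ref, alt = 1, anchor, rec.alt_allele + anchor
            else:
                # deletion or replacement: anchor on the preceding base
                if rec.pos > 1:
                    anchor = reference.fetch(chrom, rec.pos - 1, rec.pos - 1)
                    pos = rec.pos - 1
                    ref = anchor + rec.ref_allele
                    alt = anchor + rec.alt_allele
                else:
                    after = rec.pos + len(rec.ref_allele)
                    anchor = reference.fetch(chrom, after, after)
                    pos = rec.pos
                    ref = rec.ref_allele + anchor
                    alt = rec.alt_allele + anchor
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")
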