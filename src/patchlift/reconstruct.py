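"""Consensus application of a variant set to the reference genome.

:func:`apply_variants` edits each reference chromosome with that variety's
sorted variant records, producing the variety pseudomolecules together with
the :class:`~patchlift.offsets.OffsetMap` describing how coordinates moved.
Chromosomes are processed independently, one at a time.

:func:`extract_variants` is the round-trip verifier: given the reference,
the reconstructed genome and the offset map, it re-derives the variant set.
For variant sets with at least one unedited reference base between
consecutive records, ``extract_variants(*apply_variants(R, V))`` returns
exactly ``V``.
"""

from __future__ import annotations

from .errors import (
    CoordinateError,
    IntegrityError,
    ReferenceMismatchError,
    ValidationError,
)
from .genome import Genome
from .offsets import Edit, OffsetMap
from .sdi_io import VariantRecord, check_no_overlap, group_by_chrom, sort_records


def apply_variants(
    reference: Genome, variants: list[VariantRecord]
) -> tuple[Genome, OffsetMap]:
    """Edit the reference with a variety's variant set.

    Records must be non-overlapping and every reference allele must match
    the reference sequence at its position (this also guards against
    applying the same variant set twice: after one application, SNP sites
    shifted by upstream indels no longer match).
    """
    by_chrom = group_by_chrom(variants)
    unknown = set(by_chrom) - set(reference.names)
    if unknown:
        raise CoordinateError(f"variants on unknown chromosomes {sorted(unknown)}")
    check_no_overlap(variants)

    variety = Genome()
    offset_map = OffsetMap()
    for name, seq in reference:
        recs = by_chrom.get(name, [])
        pieces: list[str] = []
        edits: list[Edit] = []
        cursor = 0  # 0-based index of the next reference base to copy
        for rec in recs:
            ref, alt = rec.ref_allele, rec.alt_allele
            if ref and len(ref) == len(alt) and len(ref) > 1:
                raise ValidationError(
                    f"{name}:{rec.pos}: equal-length substitution must be "
                    "decomposed into SNPs before application"
                )
            end = rec.pos + len(ref) - 1 if ref else rec.pos
            if end > len(seq):
                raise CoordinateError(
                    f"{name}:{rec.pos}: variant extends past chromosome "
                    f"end ({len(seq)} bp)"
                )
            if ref:
                observed = seq[rec.pos - 1 : rec.pos - 1 + len(ref)]
                if observed != ref:
                    raise ReferenceMismatchError(
                        f"{name}:{rec.pos}: expected reference allele "
                        f"{ref!r}, found {observed!r}"
                    )
                pieces.append(seq[cursor : rec.pos - 1])
                pieces.append(alt)
                cursor = rec.pos - 1 + len(ref)
                if not alt:
                    edits.append(
                        Edit("del", rec.pos, end, rec.delta, (rec.pos, end))
                    )
                elif len(alt) != len(ref):
                    removed = (
                        (rec.pos + len(alt), end) if len(alt) < len(ref) else None
                    )
                    edits.append(Edit("sub", rec.pos, end, rec.delta, removed))
                # SNPs change no coordinates and need no edit
            else:
                pieces.append(seq[cursor : rec.pos])
                pieces.append(alt)
                cursor = rec.pos
                edits.append(Edit("ins", rec.pos, rec.pos, rec.delta))
        pieces.append(seq[cursor:])
        new_seq = "".join(pieces)
        expected = len(seq) + sum(r.delta for r in recs)
        if len(new_seq) != expected:
            raise IntegrityError(
                f"{name}: reconstructed length {len(new_seq)} != "
                f"reference + sum(delta) = {expected}"
            )
        variety.add(name, new_seq)
        offset_map.add_chromosome(name, len(seq), edits)
    return variety, offset_map


def extract_variants(
    reference: Genome, variety: Genome, offset_map: OffsetMap
) -> list[VariantRecord]:
    """Recover the variant set from a reconstructed genome and its map."""
    records: list[VariantRecord] = []
    for name, ref_seq in reference:
        if name not in variety or name not in offset_map:
            raise IntegrityError(f"chromosome {name!r} missing from inputs")
        var_seq = variety[name]
        edits = offset_map.edits(name)
        if len(var_seq) != len(ref_seq) + offset_map.total_delta(name):
            raise IntegrityError(
                f"{name}: sequence lengths inconsistent with offset map"
            )
        cursor = 1  # next reference base mapped 1:1
        cum = 0
        for e in edits:
            one_to_one_end = e.ref_start if e.kind == "ins" else e.ref_start - 1
            records.extend(
                _diff_segment(name, ref_seq, var_seq, cursor, one_to_one_end, cum)
            )
            if e.kind == "ins":
                start0 = e.ref_start + cum  # 0-based slice start in variety
                alt = var_seq[start0 : start0 + e.delta]
                records.append(VariantRecord(name, e.ref_start, "", alt))
            elif e.kind == "del":
                ref = ref_seq[e.ref_start - 1 : e.ref_end]
                records.append(VariantRecord(name, e.ref_start, ref, ""))
            else:  # sub
                ref = ref_seq[e.ref_start - 1 : e.ref_end]
                start0 = e.ref_start - 1 + cum
                alt = var_seq[start0 : start0 + e.alt_len]
                records.append(VariantRecord(name, e.ref_start, ref, alt))
            cum += e.delta
            cursor = e.ref_end + 1
        records.extend(
            _diff_segment(name, ref_seq, var_seq, cursor, len(ref_seq), cum)
        )
    return sort_records(records)


def _diff_segment(
    chrom: str,
    ref_seq: str,
    var_seq: str,
    start: int,
    end: int,
    offset: int,
) -> list[VariantRecord]:
    """SNP records for every mismatching base in a 1:1-mapped segment
    (1-based inclusive reference interval ``start..end``)."""
    out = []
    for pos in range(start, end + 1):
        r = ref_seq[pos - 1]
        a = var_seq[pos - 1 + offset]
        if r != a:
            out.append(VariantRecord(chrom, pos, r, a))
    return out
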