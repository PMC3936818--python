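"""Annotation coordinate translation across cumulative indels.

Transfers a reference GFF3 annotation onto a reconstructed variety genome:
every feature endpoint is shifted by the cumulative length change of the
insertions and deletions upstream of it, read off an
:class:`~patchlift.offsets.OffsetMap`.

Features wholly inside a removed interval are dropped; features with an
endpoint inside one are clamped to their surviving extent and flagged
``truncated`` (as is any parent feature that lost a child).  CDS phases
are recomputed from the lifted CDS lengths rather than copied, so that a
transcript whose exons moved stays internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import CoordinateError
from .offsets import DELETED, LiftPolicy, OffsetMap


def lift_position(
    offset_map: OffsetMap,
    chrom: str,
    pos: int,
    policy: LiftPolicy | str = LiftPolicy.REJECT,
):
    """Translate one 1-based reference coordinate.

    Returns the lifted coordinate, or :data:`~patchlift.offsets.DELETED`
    when the position was removed and ``policy`` is ``reject``.  With
    ``policy='clamp'`` a removed position maps to the last surviving base
    before its interval (0 if there is none).
    """
    if isinstance(policy, str):
        policy = LiftPolicy(policy)
    return offset_map.lift(chrom, pos, policy)


@dataclass
class LiftReportEntry:
    feature_id: str
    featuretype: str
    status: str  # lifted | truncated | dropped | unmapped_chrom
    old_start: int
    old_end: int
    new_start: int | None
    new_end: int | None


def lift_annotation(
    features: list, offset_map: OffsetMap
) -> tuple[list, list[LiftReportEntry]]:
    """Lift a list of GFF3 features (gffutils Features, file order).

    Returns the surviving lifted features (order preserved) and a report
    entry per input feature.
    """
    lifted = []
    report: list[LiftReportEntry] = []
    dropped_ids: set[str] = set()
    truncated_parents: set[str] = set()
    entries_by_id: dict[str, LiftReportEntry] = {}

    for feat in features:
        fid = feat.attributes.get("ID", [None])[0] or (
            f"{feat.featuretype}:{feat.seqid}:{feat.start}-{feat.end}"
        )
        if feat.seqid not in offset_map:
            report.append(
                LiftReportEntry(
                    fid, feat.featuretype, "unmapped_chrom",
                    feat.start, feat.end, None, None,
                )
            )
            continue
        new_start, start_hit = _lift_start(offset_map, feat.seqid, feat.start)
        new_end, end_hit = _lift_end(offset_map, feat.seqid, feat.end)
        if new_start is None or new_end is None or new_start > new_end:
            entry = LiftReportEntry(
                fid, feat.featuretype, "dropped",
                feat.start, feat.end, None, None,
            )
            report.append(entry)
            dropped_ids.add(fid)
            for parent in feat.attributes.get("Parent", []):
                truncated_parents.add(parent)
            continue
        status = "truncated" if (start_hit or end_hit) else "lifted"
        new_feat = _copy_feature(feat)
        new_feat.start = new_start
        new_feat.end = new_end
        lifted.append(new_feat)
        entry = LiftReportEntry(
            fid, feat.featuretype, status,
            feat.start, feat.end, new_start, new_end,
        )
        report.append(entry)
        entries_by_id[fid] = entry

    # propagate truncation to parents that lost a child
    changed = True
    while changed:
        changed = False
        for pid in list(truncated_parents):
            entry = entries_by_id.get(pid)
            if entry is not None and entry.status == "lifted":
                entry.status = "truncated"
                changed = True
    _recompute_phases(lifted)
    return lifted, report


def _lift_start(offset_map: OffsetMap, chrom: str, pos: int):
    """Lift a feature start; a removed start clamps forward to the first
    surviving base after its interval.  Returns (coord | None, was_hit)."""
    out = offset_map.lift(chrom, pos, LiftPolicy.REJECT)
    if out is not DELETED:
        return out, False
    # forward clamp
    interval = None
    for s, e in offset_map.deleted_intervals(chrom):
        if s <= pos <= e:
            interval = (s, e)
            break
    nxt = interval[1] + 1
    if nxt > offset_map.ref_length(chrom):
        return None, True
    return offset_map.lift(chrom, nxt, LiftPolicy.REJECT), True


def _lift_end(offset_map: OffsetMap, chrom: str, pos: int):
    """Lift a feature end; a removed end clamps back to the last surviving
    base before its interval."""
    out = offset_map.lift(chrom, pos, LiftPolicy.REJECT)
    if out is not DELETED:
        return out, False
    clamped = offset_map.lift(chrom, pos, LiftPolicy.CLAMP)
    if clamped == 0:
        return None, True
    return clamped, True


def _copy_feature(feat):
    import gffutils

    return gffutils.feature.feature_from_line(str(feat))


def _recompute_phases(features) -> None:
    """Recompute CDS phase from lifted CDS lengths, per parent transcript."""
    by_parent: dict[str, list] = {}
    for feat in features:
        if feat.featuretype == "CDS":
            for parent in feat.attributes.get("Parent", ["?"]):
                by_parent.setdefault(parent, []).append(feat)
    for parts in by_parent.values():
        strand = parts[0].strand
        ordered = sorted(parts, key=lambda f: f.start, reverse=(strand == "-"))
        cum = 0
        for feat in ordered:
            feat.frame = str((3 - cum % 3) % 3)
            cum += feat.end - feat.start + 1


def write_lift_report(report: list[LiftReportEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "feature_id\ttype\tstatus\told_start\told_end\tnew_start\tnew_end\n"
        )
        for e in report:
            fh.write(
                f"{e.feature_id}\t{e.featuretype}\t{e.status}\t"
                f"{e.old_start}\t{e.old_end}\t"
                f"{e.new_start if e.new_start is not None else 'NA'}\t"
                f"{e.new_end if e.new_end is not None else 'NA'}\n"
            )
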