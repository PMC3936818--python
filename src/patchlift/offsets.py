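"""Piecewise-constant reference→variety coordinate maps.

Applying a variant set to a reference chromosome shifts every downstream
coordinate by the cumulative length change of the insertions and deletions
upstream of it.  An :class:`OffsetMap` captures exactly that: per
chromosome, a sorted list of edits, each contributing a delta that applies
to all reference positions after its footprint, plus the reference
intervals that were removed outright.

Positions inside a removed interval have no image in the variety genome;
:meth:`OffsetMap.lift` either reports them as deleted or clamps them to the
last surviving base before the interval, at the caller's choice.

The map serialises to a chain-style tab-separated file of constant-offset
blocks (0-based half-open intervals, see :meth:`OffsetMap.write_chain`).
The chain round trip preserves lifting semantics exactly; it does not
preserve the distinction between a replacement and an adjacent
deletion+insertion pair, which lifting cannot observe.
"""

from __future__ import annotations

import enum
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path

from .errors import CoordinateError, IntegrityError, ValidationError


class LiftPolicy(enum.Enum):
    """What to do with a position that falls inside a removed interval."""

    REJECT = "reject"  # return DELETED
    CLAMP = "clamp"    # return the last surviving base before the interval


class _Deleted:
    """Singleton marker returned for positions with no image."""

    def __repr__(self) -> str:  # pragma: no cover
        return "DELETED"


DELETED = _Deleted()


@dataclass(frozen=True)
class Edit:
    """One length-changing edit on a chromosome.

    ``kind`` is ``"ins"`` (insertion after ``ref_start == ref_end``),
    ``"del"`` (deletion of ``ref_start..ref_end``) or ``"sub"``
    (replacement of ``ref_start..ref_end`` by an allele of length
    ``ref_len + delta``).  ``deleted`` is the removed reference interval,
    if any.
    """

    kind: str
    ref_start: int
    ref_end: int
    delta: int
    deleted: tuple[int, int] | None = None

    @property
    def ref_len(self) -> int:
        return 0 if self.kind == "ins" else self.ref_end - self.ref_start + 1

    @property
    def alt_len(self) -> int:
        return self.ref_len + self.delta


class _ChromMap:
    def __init__(self, length: int, edits: list[Edit]):
        self.length = length
        self.edits = edits
        self._keys = [e.ref_end for e in edits]
        self._cum: list[int] = []
        total = 0
        for e in edits:
            total += e.delta
            self._cum.append(total)
        # strictly increasing breakpoints
        for a, b in zip(self._keys, self._keys[1:]):
            if b <= a:
                raise IntegrityError("offset-map breakpoints not increasing")
        self._del_starts = [e.deleted[0] for e in edits if e.deleted]
        self._del_ends = [e.deleted[1] for e in edits if e.deleted]
        for a, b in zip(self._del_ends, self._del_starts[1:]):
            if b <= a:
                raise IntegrityError("deleted intervals overlap")

    @property
    def total_delta(self) -> int:
        return self._cum[-1] if self._cum else 0

    def cum_before(self, pos: int) -> int:
        """Cumulative delta contributed by edits whose footprint ends before
        ``pos``."""
        i = bisect_left(self._keys, pos)
        return self._cum[i - 1] if i else 0

    def deleted_interval_of(self, pos: int) -> tuple[int, int] | None:
        i = bisect_right(self._del_starts, pos) - 1
        if i >= 0 and pos <= self._del_ends[i]:
            return (self._del_starts[i], self._del_ends[i])
        return None


class OffsetMap:
    """Per-chromosome reference→variety coordinate translation."""

    def __init__(self) -> None:
        self._chroms: dict[str, _ChromMap] = {}
        self._order: list[str] = []

    def add_chromosome(self, name: str, length: int, edits: list[Edit]) -> None:
        if name in self._chroms:
            raise ValidationError(f"duplicate chromosome {name!r}")
        self._order.append(name)
        self._chroms[name] = _ChromMap(length, sorted(edits, key=lambda e: e.ref_end))

    @property
    def chromosomes(self) -> list[str]:
        return list(self._order)

    def __contains__(self, name: str) -> bool:
        return name in self._chroms

    def edits(self, chrom: str) -> list[Edit]:
        return list(self._chroms[chrom].edits)

    def ref_length(self, chrom: str) -> int:
        return self._chroms[chrom].length

    def total_delta(self, chrom: str) -> int:
        return self._chroms[chrom].total_delta

    def deleted_intervals(self, chrom: str) -> list[tuple[int, int]]:
        cm = self._chroms[chrom]
        return list(zip(cm._del_starts, cm._del_ends))

    def lift(
        self,
        chrom: str,
        pos: int,
        policy: LiftPolicy = LiftPolicy.REJECT,
    ) -> int | _Deleted:
        """Translate a 1-based reference position to the variety genome.

        Returns :data:`DELETED` (policy ``REJECT``) or the coordinate of the
        last surviving base before the removed interval (policy ``CLAMP``;
        0 when the interval starts at base 1) for positions without an
        image.
        """
        if chrom not in self._chroms:
            raise CoordinateError(f"unknown chromosome {chrom!r}")
        cm = self._chroms[chrom]
        if not (1 <= pos <= cm.length):
            raise CoordinateError(f"{chrom}:{pos} outside 1..{cm.length}")
        interval = cm.deleted_interval_of(pos)
        if interval is not None:
            if policy is LiftPolicy.REJECT:
                return DELETED
            start = interval[0]
            if start <= 1:
                return 0
            return self.lift(chrom, start - 1, policy)
        return pos + cm.cum_before(pos)

    # -- chain serialization -------------------------------------------------

    def write_chain(self, path: str | Path) -> None:
        """Write constant-offset blocks as TSV.

        Columns: chrom, start, end (0-based half-open reference interval),
        offset — where offset is either the integer to add to a 1-based
        reference position in the block, or the literal ``del`` for a
        removed interval.
        """
        with open(path, "w") as fh:
            fh.write("# patchlift chain: 0-based half-open reference intervals\n")
            fh.write("#chrom\tstart\tend\toffset\n")
            for name in self._order:
                cm = self._chroms[name]
                cur = 1
                cum = 0
                for e in cm.edits:
                    survive_end = (e.deleted[0] - 1) if e.deleted else e.ref_end
                    if cur <= survive_end:
                        fh.write(f"{name}\t{cur - 1}\t{survive_end}\t{cum}\n")
                    if e.deleted:
                        fh.write(
                            f"{name}\t{e.deleted[0] - 1}\t{e.deleted[1]}\tdel\n"
                        )
                    cum += e.delta
                    cur = e.ref_end + 1
                if cur <= cm.length:
                    fh.write(f"{name}\t{cur - 1}\t{cm.length}\t{cum}\n")

    @classmethod
    def read_chain(cls, path: str | Path) -> "OffsetMap":
        rows: dict[str, list[tuple[int, int, str]]] = {}
        order: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                chrom, s, e, off = line.split("\t")
                if chrom not in rows:
                    rows[chrom] = []
                    order.append(chrom)
                rows[chrom].append((int(s), int(e), off))
        out = cls()
        for chrom in order:
            edits: list[Edit] = []
            cum = 0
            length = rows[chrom][-1][1]
            for start0, end0, off in rows[chrom]:
                if off == "del":
                    s, e = start0 + 1, end0
                    edits.append(Edit("del", s, e, -(e - s + 1), (s, e)))
                    cum -= e - s + 1
                else:
                    offset = int(off)
                    if offset != cum:
                        gain = offset - cum
                        if gain <= 0:
                            raise IntegrityError(
                                f"{chrom}: non-monotone offsets in chain file"
                            )
                        edits.append(Edit("ins", start0, start0, gain))
                        cum = offset
            out.add_chromosome(chrom, length, edits)
        return out
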