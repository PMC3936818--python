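"""Ordered, named nucleotide sequences with FASTA round trip.

A :class:`Genome` is little more than an ordered mapping from chromosome
name to sequence, but it is the unit every stage of the pipeline exchanges:
the reference read from FASTA, and the reconstructed variety pseudomolecules
written back out.  Sequences are stored as plain upper-case strings over the
IUPAC nucleotide alphabet; chromosomes are processed one at a time, so no
stage ever requires more than one chromosome's worth of working copies.
"""

from __future__ import annotations

from collections.abc import Iterator
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError

#: Every code a sequence may contain (ambiguity codes included).
IUPAC_ALPHABET = frozenset("ACGTNRYSWKMBDHV")


class Genome:
    """An ordered collection of named chromosome sequences."""

    def __init__(self, chromosomes: list[tuple[str, str]] | None = None):
        self._names: list[str] = []
        self._seqs: dict[str, str] = {}
        for name, seq in chromosomes or []:
            self.add(name, seq)

    def add(self, name: str, sequence: str) -> None:
        if name in self._seqs:
            raise ValidationError(f"duplicate chromosome name {name!r}")
        sequence = sequence.upper()
        bad = set(sequence) - IUPAC_ALPHABET
        if bad:
            raise ValidationError(
                f"chromosome {name!r} contains non-IUPAC characters {sorted(bad)}"
            )
        self._names.append(name)
        self._seqs[name] = sequence

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __iter__(self) -> Iterator[tuple[str, str]]:
        for name in self._names:
            yield name, self._seqs[name]

    def __len__(self) -> int:
        return len(self._names)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return list(self) == list(other)

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def fetch(self, name: str, start: int, end: int) -> str:
        """Return bases ``start..end`` (1-based, inclusive)."""
        seq = self._seqs[name]
        if not (1 <= start <= end <= len(seq)):
            raise ValidationError(
                f"{name}:{start}-{end} outside 1..{len(seq)}"
            )
        return seq[start - 1 : end]


def read_fasta(path: str | Path) -> Genome:
    genome = Genome()
    for rec in SeqIO.parse(str(path), "fasta"):
        genome.add(rec.id, str(rec.seq))
    return genome


def write_fasta(genome: Genome, path: str | Path, width: int = 60) -> None:
    records = (
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome
    )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
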