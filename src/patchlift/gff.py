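"""Thin GFF3 helpers shared by the liftover and effect modules.

Parsing is delegated to :mod:`gffutils`; this module only adds streaming
read/write of feature lists (file order preserved) and assembly of
:class:`GeneModel` objects — strand-aware genes with exon/CDS/UTR interval
lists — from a GFF3 file via an in-memory gffutils database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from gffutils.iterators import DataIterator
from Bio.Seq import Seq

from .errors import ValidationError
from .genome import Genome

_UTR_TYPES = {"five_prime_UTR", "three_prime_UTR", "UTR"}

STOP_CODONS = {"TAA", "TAG", "TGA"}


def read_gff(path: str | Path) -> list[gffutils.Feature]:
    """All features of a GFF3 file, in file order."""
    return list(DataIterator(str(path)))


def write_gff(features, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            fh.write(str(feat) + "\n")


@dataclass
class GeneModel:
    """A protein-coding gene as the unit of effect classification.

    All intervals are 1-based inclusive genomic coordinates, sorted and
    non-overlapping.  ``cds`` intervals are a subset of ``exons``.  A model
    whose spliced CDS is not a canonical ORF (ATG start, single terminal
    stop, length divisible by 3) is flagged ``non_canonical`` but still
    processed.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    utrs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        self.utrs = sorted(self.utrs)
        for a, b in zip(self.cds, self.cds[1:]):
            if b[0] <= a[1]:
                raise ValidationError(f"{self.gene_id}: overlapping CDS intervals")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons (genomic order)."""
        return [
            (a[1] + 1, b[0] - 1)
            for a, b in zip(self.exons, self.exons[1:])
            if b[0] - a[1] > 1
        ]

    def splice_windows(self, width: int = 2) -> list[tuple[int, int]]:
        """The first and last ``width`` bases of every intron — the
        canonical GT/AG dinucleotides when ``width`` is 2."""
        windows = []
        for s, e in self.introns():
            if e - s + 1 <= 2 * width:
                windows.append((s, e))
            else:
                windows.append((s, s + width - 1))
                windows.append((e - width + 1, e))
        return windows

    def cds_sequence(self, genome: Genome) -> str:
        """Spliced CDS on the coding strand."""
        parts = [genome.fetch(self.chrom, s, e) for s, e in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def protein(self, genome: Genome) -> str:
        return str(Seq(self.cds_sequence(genome)).translate())

    def cds_local_position(self, pos: int) -> int | None:
        """1-based position within the spliced CDS (coding strand) of a
        genomic position, or None if outside the CDS."""
        offset = 0
        if self.strand == "+":
            for s, e in self.cds:
                if s <= pos <= e:
                    return offset + (pos - s) + 1
                offset += e - s + 1
        else:
            for s, e in reversed(self.cds):
                if s <= pos <= e:
                    return offset + (e - pos) + 1
                offset += e - s + 1
        return None

    def genomic_position_of_cds_local(self, local: int) -> int:
        """Inverse of :meth:`cds_local_position`: genomic coordinate of the
        1-based spliced-CDS position ``local`` (coding strand)."""
        if not (1 <= local <= self.cds_length):
            raise ValidationError(
                f"{self.gene_id}: CDS position {local} outside 1..{self.cds_length}"
            )
        offset = 0
        intervals = self.cds if self.strand == "+" else list(reversed(self.cds))
        for s, e in intervals:
            size = e - s + 1
            if local <= offset + size:
                within = local - offset - 1
                return s + within if self.strand == "+" else e - within
            offset += size
        raise ValidationError("unreachable")  # pragma: no cover

    def is_canonical(self, genome: Genome) -> bool:
        seq = self.cds_sequence(genome)
        if len(seq) % 3 != 0 or not seq.startswith("ATG"):
            return False
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        return codons[-1] in STOP_CODONS and not any(
            c in STOP_CODONS for c in codons[:-1]
        )


def gene_models_from_gff(path: str | Path) -> list[GeneModel]:
    """Assemble one GeneModel per gene from a GFF3 file.

    Genes with several mRNA children use the first (file-order) transcript
    as the representative model.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        transcripts = list(db.children(gene, featuretype="mRNA", order_by="start"))
        parent = transcripts[0] if transcripts else gene
        exons = [
            (f.start, f.end) for f in db.children(parent, featuretype="exon")
        ]
        cds = [(f.start, f.end) for f in db.children(parent, featuretype="CDS")]
        utrs = [
            (f.start, f.end)
            for t in _UTR_TYPES
            for f in db.children(parent, featuretype=t)
        ]
        if not exons:
            exons = cds or [(gene.start, gene.end)]
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds=cds,
                utrs=utrs,
            )
        )
    return models
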