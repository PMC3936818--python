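"""Synthetic reference genomes, gene models and paired variant sets.

Emulates the data shape of a two-variety resequencing study of a
homozygous-inbred crop against one reference: a random reference genome
carrying canonical protein-coding gene models (ATG start, single terminal
stop, GT..AG introns, UTRs), and two variety variant sets in which SNPs
are mostly variety-specific while indels are mostly shared, a small
fraction of SNP calls is ambiguous (IUPAC heterozygous-like codes), and
indel lengths mix a short geometric body with a rare multi-hundred-bp
tail.  On top of the random background, configurable quotas of coding
effects (synonymous, missense, frameshift, start/stop alterations,
splice-site hits) are engineered deterministically at sites that
guarantee the intended effect, each verified internally by translating
the full mutant CDS.

Every emitted variant carries a :class:`TruthRecord` with its intended
class, genomic context, coding effect, owning gene and variety
membership, so each pipeline stage can be scored against ground truth.
Identical seeds give byte-identical output bundles.
"""

from __future__ import annotations

import itertools
import json
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .errors import PatchliftError, ValidationError
from .genome import Genome, write_fasta
from .gff import GeneModel, STOP_CODONS
from .sdi_io import VariantRecord, classify_variant, sort_records, write_sdi

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: IUPAC two-base ambiguity code for an unordered base pair.
_IUPAC_PAIR = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}

_DEFAULT_QUOTAS: dict[str, int] = {
    "synonymous": 4,
    "missense": 4,
    "frameshift": 3,
    "start_lost": 2,
    "stop_gained": 2,
    "splice_disrupted": 3,
}

#: Row labels of the fruit-quality gene-class report, with the class sizes
#: used by the paper-shaped preset (scaled to a few-hundred-gene genome).
PAPER_SHAPED_CLASSES: dict[str, int] = {
    "Ascorbate biosynthesis": 10,
    "MEP/carotenoid pathway": 14,
    "Ethylene-related genes": 20,
    "Cell wall": 80,
    "Transcription factors": 180,
    "Transcription regulators": 48,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    Rates are per base pair.  The defaults mirror the shape of the real
    data: ~3.3% ambiguous SNPs, mostly variety-specific SNPs
    (``shared_fraction_snp``), majority-shared indels
    (``shared_fraction_indel``), and indel lengths drawn from a 1–5 bp
    geometric body with a rare 100–5,000 bp tail.
    """

    seed: int = 0
    preset: str = "default"
    chrom_lengths: tuple[int, ...] = (150_000, 150_000)
    gc_fraction: float = 0.36
    gene_count: int = 60
    exons_per_gene: tuple[int, int] = (2, 5)
    cds_codons: tuple[int, int] = (60, 180)
    utr5_length: tuple[int, int] = (50, 200)
    utr3_length: tuple[int, int] = (50, 200)
    intron_length: tuple[int, int] = (80, 400)
    intergenic_spacing: tuple[int, int] = (600, 2_000)
    snp_rate: float = 2e-3
    indel_rate: float = 4e-4
    indel_geom_p: float = 0.55
    indel_tail_prob: float = 0.01
    indel_tail_range: tuple[int, int] = (100, 5_000)
    max_insertion: int = 5_000
    max_deletion: int = 36_000
    insertion_prob: float = 0.6
    unbalanced_fraction: float = 0.05
    shared_fraction_snp: float = 0.02
    shared_fraction_indel: float = 0.65
    ambiguous_fraction: float = 0.033
    effect_quotas: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_QUOTAS)
    )
    window: int = 5_000

    def validate(self) -> None:
        for name in (
            "snp_rate", "indel_rate", "indel_tail_prob", "insertion_prob",
            "unbalanced_fraction", "shared_fraction_snp",
            "shared_fraction_indel", "ambiguous_fraction", "gc_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if sum(self.effect_quotas.values()) > self.gene_count:
            raise ValidationError(
                "effect quotas exceed gene count: one engineered variant "
                "is placed per gene"
            )
        unknown = set(self.effect_quotas) - {
            "synonymous", "missense", "frameshift", "inframe_indel",
            "start_lost", "stop_lost", "stop_gained", "splice_disrupted",
        }
        if unknown:
            raise ValidationError(f"unknown effect quotas {sorted(unknown)}")


def preset_config(name: str, seed: int = 0) -> SimConfig:
    """The two shipped presets: ``default`` (small, fast) and
    ``paper-shaped`` (a few hundred genes in six named classes, with a
    deleterious-score table of 386 scored genes of which 45 pass the
    conventional cutoff)."""
    if name == "default":
        return SimConfig(seed=seed)
    if name == "paper-shaped":
        return SimConfig(
            seed=seed,
            preset="paper-shaped",
            chrom_lengths=(650_000, 650_000),
            gene_count=400,
        )
    raise ValidationError(f"unknown preset {name!r}")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one emitted variant."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_class: str
    context: str | None
    effect: str | None
    gene_id: str | None
    membership: str  # "A" | "B" | "both"
    engineered: bool = False

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class SimBundle:
    config: SimConfig
    reference: Genome
    models: list[GeneModel]
    variants_a: list[VariantRecord]
    variants_b: list[VariantRecord]
    truth: list[TruthRecord]


# ---------------------------------------------------------------------------
# genome and gene models


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    # independent, seed-derived stream per stage
    return np.random.default_rng([stage, config.seed])


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])


def generate_genome(config: SimConfig) -> Genome:
    """A random background genome at the configured lengths and GC."""
    config.validate()
    rng = _rng(config, 0)
    genome = Genome()
    for i, length in enumerate(config.chrom_lengths, start=1):
        genome.add(f"chr{i:02d}", _random_bases(rng, length, config.gc_fraction))
    return genome


_SENSE_CODONS = sorted(
    c
    for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
    if c not in STOP_CODONS
)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Canonical ORF: ATG, non-stop body, one terminal stop."""
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    stop = sorted(STOP_CODONS)[rng.integers(0, 3)]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + stop


def _composition(
    rng: np.random.Generator, total: int, parts: int, minimum: int
) -> list[int]:
    """Split ``total`` into ``parts`` pieces each >= minimum."""
    if parts * minimum > total:
        raise ValidationError("transcript too short for requested exon count")
    free = total - parts * minimum
    cuts = np.sort(rng.integers(0, free + 1, size=parts - 1))
    sizes = np.diff(np.concatenate([[0], cuts, [free]]))
    return [int(s) + minimum for s in sizes]


def generate_gene_models(
    genome: Genome, config: SimConfig
) -> tuple[list[GeneModel], Genome]:
    """Place non-overlapping canonical genes on both strands.

    Returns the gene models and a copy of the genome with the gene loci
    written into the sequence (so every model's CDS really is a canonical
    ORF in that genome).
    """
    config.validate()
    rng = _rng(config, 1)
    chroms = {name: list(seq) for name, seq in genome}
    models: list[GeneModel] = []
    remaining = config.gene_count
    gene_no = 0
    for name, _ in genome:
        seq = chroms[name]
        length = len(seq)
        cursor = int(rng.integers(*config.intergenic_spacing))
        while remaining > 0:
            gene = _build_gene(rng, config)
            start = cursor + 1  # 1-based gene start
            end = start + len(gene["seq"]) - 1
            if end + config.intergenic_spacing[1] > length:
                break
            gene_no += 1
            gid = f"gene{gene_no:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            gseq = gene["seq"]
            if strand == "-":
                gseq = gseq.translate(_COMPLEMENT)[::-1]
            seq[start - 1 : end] = list(gseq)
            L = len(gene["seq"])

            def to_genomic(local: tuple[int, int]) -> tuple[int, int]:
                a, b = local
                if strand == "+":
                    return (start + a - 1, start + b - 1)
                return (start + L - b, start + L - a)

            models.append(
                GeneModel(
                    gene_id=gid,
                    chrom=name,
                    strand=strand,
                    exons=[to_genomic(iv) for iv in gene["exons"]],
                    cds=[to_genomic(iv) for iv in gene["cds"]],
                    utrs=[to_genomic(iv) for iv in gene["utrs"]],
                )
            )
            remaining -= 1
            cursor = end + int(rng.integers(*config.intergenic_spacing))
    if remaining > 0:
        raise ValidationError(
            f"genome too small: {remaining} of {config.gene_count} genes "
            "could not be placed"
        )
    out = Genome([(name, "".join(chroms[name])) for name, _ in genome])
    for model in models:
        if not model.is_canonical(out):
            raise PatchliftError(
                f"internal error: generated gene {model.gene_id} not canonical"
            )
    return models, out


def _build_gene(rng: np.random.Generator, config: SimConfig) -> dict:
    """One gene in sense orientation, with local 1-based intervals."""
    n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
    n_codons = int(rng.integers(config.cds_codons[0], config.cds_codons[1] + 1))
    u5 = int(rng.integers(*config.utr5_length))
    u3 = int(rng.integers(*config.utr3_length))
    cds = _random_cds(rng, n_codons)
    transcript = _random_bases(rng, u5, config.gc_fraction) + cds + _random_bases(
        rng, u3, config.gc_fraction
    )
    exon_sizes = _composition(rng, len(transcript), n_ex, minimum=30)
    intron_sizes = [
        int(rng.integers(*config.intron_length)) for _ in range(n_ex - 1)
    ]
    pieces: list[str] = []
    exons_local: list[tuple[int, int]] = []
    t_cursor = 0  # transcript bases consumed
    g_cursor = 0  # gene-local bases emitted
    t_ranges: list[tuple[int, int]] = []  # transcript interval per exon
    for i, size in enumerate(exon_sizes):
        pieces.append(transcript[t_cursor : t_cursor + size])
        exons_local.append((g_cursor + 1, g_cursor + size))
        t_ranges.append((t_cursor + 1, t_cursor + size))
        t_cursor += size
        g_cursor += size
        if i < n_ex - 1:
            ilen = intron_sizes[i]
            intron = "GT" + _random_bases(rng, ilen - 4, config.gc_fraction) + "AG"
            pieces.append(intron)
            g_cursor += ilen
    gene_seq = "".join(pieces)

    cds_t = (u5 + 1, u5 + len(cds))  # transcript interval of the CDS
    cds_local: list[tuple[int, int]] = []
    utrs_local: list[tuple[int, int]] = []
    for (ts, te), (gs, ge) in zip(t_ranges, exons_local):
        lo = max(ts, cds_t[0])
        hi = min(te, cds_t[1])
        if lo <= hi:
            cds_local.append((gs + (lo - ts), gs + (hi - ts)))
        if ts < cds_t[0]:
            utrs_local.append((gs, gs + min(te, cds_t[0] - 1) - ts))
        if te > cds_t[1]:
            utrs_local.append((gs + max(ts, cds_t[1] + 1) - ts, ge))
    return {
        "seq": gene_seq,
        "exons": exons_local,
        "cds": cds_local,
        "utrs": utrs_local,
    }


# ---------------------------------------------------------------------------
# truth labelling (independent of the effects module: full-CDS translation)


def protein_diff_effect(
    gene: GeneModel, variant: VariantRecord, reference: Genome
) -> str:
    """Effect of a CDS SNV by translating the full mutant CDS and diffing
    the proteins — the oracle route, no codon arithmetic."""
    local = gene.cds_local_position(variant.pos)
    if local is None:
        raise PatchliftError("variant outside CDS")
    cds = gene.cds_sequence(reference)
    alt = variant.alt_allele
    if gene.strand == "-":
        alt = alt.translate(_COMPLEMENT)[::-1]
    mutant = cds[: local - 1] + alt + cds[local:]
    ref_prot = str(Seq(cds).translate())
    mut_prot = str(Seq(mutant).translate())
    if ref_prot == mut_prot:
        return "synonymous"
    diffs = [i for i, (a, b) in enumerate(zip(ref_prot, mut_prot)) if a != b]
    i = diffs[0]
    if i == 0:
        return "start_lost"
    if mut_prot[i] == "*" and ref_prot[i] != "*":
        return "stop_gained"
    if ref_prot[i] == "*" and mut_prot[i] != "*":
        return "stop_lost"
    return "missense"


class _TruthLabeller:
    """Interval arithmetic over the generated models, used to label the
    intended context of background variants."""

    def __init__(self, models: Sequence[GeneModel], window: int):
        self.window = window
        self.by_chrom: dict[str, list[GeneModel]] = {}
        for m in sorted(models, key=lambda m: (m.chrom, m.start)):
            self.by_chrom.setdefault(m.chrom, []).append(m)
        self.starts = {
            c: [m.start for m in ms] for c, ms in self.by_chrom.items()
        }

    def context(
        self, chrom: str, fp: tuple[int, int]
    ) -> tuple[str, GeneModel | None]:
        models = self.by_chrom.get(chrom, [])
        if not models:
            return "intergenic", None
        i = bisect_right(self.starts[chrom], fp[1])
        candidates = models[max(0, i - 4) : i + 1]
        in_span = [m for m in candidates if fp[0] <= m.end and m.start <= fp[1]]
        if in_span:
            m = in_span[0]
            if any(fp[0] <= e and s <= fp[1] for s, e in m.cds):
                return "CDS", m
            if any(fp[0] <= e and s <= fp[1] for s, e in m.splice_windows()):
                return "splice_site", m
            if any(fp[0] <= e and s <= fp[1] for s, e in m.utrs):
                return "UTR", m
            return "intronic", m
        near = [
            m
            for m in candidates
            if fp[0] <= m.end + self.window and m.start - self.window <= fp[1]
        ]
        if not near:
            return "intergenic", None
        m = min(near, key=lambda m: min(abs(m.start - fp[1]), abs(fp[0] - m.end)))
        before = fp[1] < m.start
        if m.strand == "+":
            return ("upstream" if before else "downstream"), m
        return ("downstream" if before else "upstream"), m


# ---------------------------------------------------------------------------
# variant placement


class _Blocker:
    """Per-chromosome occupancy of variant footprints plus a 1 bp guard,
    so no two variants touch the same base and round trips stay exact."""

    def __init__(self, genome: Genome):
        self.blocked = {
            name: np.zeros(len(seq) + 2, dtype=bool) for name, seq in genome
        }

    def is_free(self, chrom: str, start: int, end: int) -> bool:
        b = self.blocked[chrom]
        lo = max(0, start - 1)
        hi = min(len(b), end + 2)
        return not b[lo:hi].any()

    def block(self, chrom: str, start: int, end: int) -> None:
        b = self.blocked[chrom]
        b[max(0, start - 1) : min(len(b), end + 2)] = True

    def free_positions(self, chrom: str) -> np.ndarray:
        b = self.blocked[chrom]
        return np.flatnonzero(~b[1:-1]) + 1  # 1-based


def _membership(rng: np.random.Generator, shared_fraction: float) -> str:
    if rng.random() < shared_fraction:
        return "both"
    return "A" if rng.random() < 0.5 else "B"


def generate_variant_sets(
    genome: Genome, models: Sequence[GeneModel], config: SimConfig
) -> tuple[list[VariantRecord], list[VariantRecord], list[TruthRecord]]:
    """Two varieties' variant sets plus one truth record per variant.

    Engineered effect quotas are placed first (one per gene, exact counts,
    verified by full-CDS translation); background SNPs and indels are then
    drawn at the configured rates with the configured sharing and
    ambiguity.  No two variants touch the same reference base.
    """
    config.validate()
    rng = _rng(config, 2)
    blocker = _Blocker(genome)
    labeller = _TruthLabeller(models, config.window)
    truth: list[TruthRecord] = []

    # -- engineered quotas
    order = [models[i] for i in rng.permutation(len(models))]
    used: set[str] = set()
    membership_cycle = ["A", "B", "both"]
    cycle_i = 0
    for effect in sorted(config.effect_quotas):
        quota = config.effect_quotas[effect]
        placed = 0
        for gene in order:
            if placed == quota:
                break
            if gene.gene_id in used:
                continue
            engineered = _engineer_effect(rng, gene, genome, effect)
            if engineered is None:
                continue
            variant, context = engineered
            fs, fe = variant.footprint()
            if not blocker.is_free(variant.chrom, fs, fe):
                continue
            blocker.block(variant.chrom, fs, fe)
            used.add(gene.gene_id)
            membership = membership_cycle[cycle_i % 3]
            cycle_i += 1
            truth.append(
                TruthRecord(
                    variant.chrom, variant.pos,
                    variant.ref_allele, variant.alt_allele,
                    classify_variant(variant).value,
                    context, effect, gene.gene_id, membership,
                    engineered=True,
                )
            )
            placed += 1
        if placed < quota:
            raise ValidationError(
                f"could not place effect quota {effect!r}: "
                f"{placed} of {quota} sites found"
            )

    # -- background SNPs
    for name, seq in genome:
        n = int(rng.poisson(len(seq) * config.snp_rate))
        free = blocker.free_positions(name)
        n = min(n, free.size)
        positions = np.sort(rng.choice(free, size=n, replace=False))
        for pos in positions:
            pos = int(pos)
            if not blocker.is_free(name, pos, pos):
                continue
            ref = seq[pos - 1]
            if ref not in "ACGT":
                continue
            alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
            ambiguous = rng.random() < config.ambiguous_fraction
            if ambiguous:
                alt = _IUPAC_PAIR[frozenset((ref, alt))]
            variant = VariantRecord(name, pos, ref, alt)
            blocker.block(name, pos, pos)
            context, gene = labeller.context(name, (pos, pos))
            effect = None
            if context == "CDS" and not ambiguous:
                effect = protein_diff_effect(gene, variant, genome)
            elif context == "splice_site" and not ambiguous:
                effect = "splice_disrupted"
            truth.append(
                TruthRecord(
                    name, pos, ref, alt, "SNP", context, effect,
                    gene.gene_id if gene else None,
                    _membership(rng, config.shared_fraction_snp),
                )
            )

    # -- background indels
    for name, seq in genome:
        n = int(rng.poisson(len(seq) * config.indel_rate))
        for _ in range(n):
            rec = _place_indel(rng, name, seq, blocker, config)
            if rec is None:
                continue
            fs, fe = rec.footprint()
            blocker.block(name, fs, fe)
            context, gene = labeller.context(name, (fs, fe))
            effect = None
            if context == "CDS":
                effect = "frameshift" if rec.delta % 3 != 0 else "inframe_indel"
            elif context == "splice_site":
                effect = "splice_disrupted"
            truth.append(
                TruthRecord(
                    name, rec.pos, rec.ref_allele, rec.alt_allele,
                    classify_variant(rec).value, context, effect,
                    gene.gene_id if gene else None,
                    _membership(rng, config.shared_fraction_indel),
                )
            )

    truth.sort(key=lambda t: (t.chrom, t.pos, t.ref_allele, t.alt_allele))
    variants_a = [
        VariantRecord(t.chrom, t.pos, t.ref_allele, t.alt_allele)
        for t in truth
        if t.membership in ("A", "both")
    ]
    variants_b = [
        VariantRecord(t.chrom, t.pos, t.ref_allele, t.alt_allele)
        for t in truth
        if t.membership in ("B", "both")
    ]
    return sort_records(variants_a), sort_records(variants_b), truth


def _indel_length(rng: np.random.Generator, config: SimConfig, cap: int) -> int:
    if rng.random() < config.indel_tail_prob:
        lo, hi = config.indel_tail_range
        hi = min(hi, cap)
        # log-uniform over the long tail
        return int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return min(int(rng.geometric(config.indel_geom_p)), 5)


def _place_indel(
    rng: np.random.Generator,
    chrom: str,
    seq: str,
    blocker: _Blocker,
    config: SimConfig,
) -> VariantRecord | None:
    """One background indel; None when no free site is found quickly."""
    for _ in range(30):
        r = rng.random()
        if r < config.unbalanced_fraction:
            ref_len = int(rng.integers(1, 4))
            gain = _indel_length(rng, config, config.max_insertion)
            alt_len = ref_len + max(gain, 1)
            pos = int(rng.integers(2, len(seq) - ref_len))
            if not blocker.is_free(chrom, pos, pos + ref_len - 1):
                continue
            ref = seq[pos - 1 : pos - 1 + ref_len]
            if set(ref) - set("ACGT"):
                continue
            alt = _random_bases(rng, alt_len, config.gc_fraction)
            if alt[:ref_len] == ref:  # keep it a true replacement
                alt = ("ACGT".replace(ref[0], "")[0]) + alt[1:]
            return VariantRecord(chrom, pos, ref, alt)
        if r < config.unbalanced_fraction + (1 - config.unbalanced_fraction) * (
            config.insertion_prob
        ):
            length = _indel_length(rng, config, config.max_insertion)
            pos = int(rng.integers(1, len(seq) - 1))
            if not blocker.is_free(chrom, pos, pos + 1):
                continue
            return VariantRecord(
                chrom, pos, "", _random_bases(rng, length, config.gc_fraction)
            )
        length = _indel_length(rng, config, config.max_deletion)
        if length >= len(seq) - 2:
            continue
        pos = int(rng.integers(2, len(seq) - length))
        if not blocker.is_free(chrom, pos, pos + length - 1):
            continue
        ref = seq[pos - 1 : pos - 1 + length]
        if set(ref) - set("ACGT"):
            continue
        return VariantRecord(chrom, pos, ref, "")
    return None


def _engineer_effect(
    rng: np.random.Generator,
    gene: GeneModel,
    genome: Genome,
    effect: str,
) -> tuple[VariantRecord, str] | None:
    """A variant in this gene guaranteed to realize ``effect``, or None if
    the gene offers no suitable site.  SNV effects are verified by the
    full-CDS translation oracle."""
    cds = gene.cds_sequence(genome)
    n_codons = len(cds) // 3

    def snv_at_local(local: int, sense_alt: str) -> VariantRecord:
        gpos = gene.genomic_position_of_cds_local(local)
        gref = genome.fetch(gene.chrom, gpos, gpos)
        galt = sense_alt if gene.strand == "+" else sense_alt.translate(_COMPLEMENT)
        return VariantRecord(gene.chrom, gpos, gref, galt)

    if effect in ("synonymous", "missense", "stop_gained"):
        codon_order = 1 + rng.permutation(n_codons - 2)
        for ci in codon_order:
            codon = cds[ci * 3 : ci * 3 + 3]
            for within in range(3):
                for alt in "ACGT":
                    if alt == codon[within]:
                        continue
                    mutant = codon[:within] + alt + codon[within + 1 :]
                    ref_aa = str(Seq(codon).translate())
                    alt_aa = str(Seq(mutant).translate())
                    ok = (
                        (effect == "synonymous" and ref_aa == alt_aa)
                        or (
                            effect == "missense"
                            and alt_aa not in (ref_aa, "*")
                        )
                        or (effect == "stop_gained" and alt_aa == "*")
                    )
                    if ok:
                        variant = snv_at_local(int(ci) * 3 + within + 1, alt)
                        assert protein_diff_effect(gene, variant, genome) == effect
                        return variant, "CDS"
        return None
    if effect == "start_lost":
        within = int(rng.integers(0, 3))
        ref_base = "ATG"[within]
        alt = "ACGT".replace(ref_base, "")[rng.integers(0, 3)]
        mutant = "ATG"[:within] + alt + "ATG"[within + 1 :]
        if mutant == "ATG":  # pragma: no cover
            return None
        variant = snv_at_local(within + 1, alt)
        assert protein_diff_effect(gene, variant, genome) in (
            "start_lost",
        )
        return variant, "CDS"
    if effect == "stop_lost":
        stop = cds[-3:]
        for within in range(3):
            for alt in "ACGT":
                if alt == stop[within]:
                    continue
                mutant = stop[:within] + alt + stop[within + 1 :]
                if mutant not in STOP_CODONS:
                    variant = snv_at_local(len(cds) - 3 + within + 1, alt)
                    assert protein_diff_effect(gene, variant, genome) == "stop_lost"
                    return variant, "CDS"
        return None  # pragma: no cover
    if effect in ("frameshift", "inframe_indel"):
        size = 3 if effect == "inframe_indel" else int(rng.integers(1, 3))
        # an interior site of the largest CDS segment, clear of start/stop
        seg = max(gene.cds, key=lambda iv: iv[1] - iv[0])
        lo, hi = seg[0] + 9, seg[1] - 9 - size
        if hi <= lo:
            return None
        pos = int(rng.integers(lo, hi))
        ref = genome.fetch(gene.chrom, pos, pos + size - 1)
        return VariantRecord(gene.chrom, pos, ref, ""), "CDS"
    if effect == "splice_disrupted":
        introns = gene.introns()
        if not introns:
            return None
        s, e = introns[int(rng.integers(0, len(introns)))]
        pos = s if rng.random() < 0.5 else e
        ref = genome.fetch(gene.chrom, pos, pos)
        alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
        assert any(
            ws <= pos <= we for ws, we in gene.splice_windows()
        )
        return VariantRecord(gene.chrom, pos, ref, alt), "splice_site"
    raise ValidationError(f"unknown engineered effect {effect!r}")


# ---------------------------------------------------------------------------
# bundles


def simulate(config: SimConfig) -> SimBundle:
    """Run the three generation stages and return everything in memory."""
    background = generate_genome(config)
    models, reference = generate_gene_models(background, config)
    variants_a, variants_b, truth = generate_variant_sets(
        reference, models, config
    )
    return SimBundle(config, reference, models, variants_a, variants_b, truth)


def write_truth(truth: Sequence[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tclass\tcontext\teffect\tgene\t"
            "membership\tengineered\n"
        )
        for t in truth:
            fh.write(
                f"{t.chrom}\t{t.pos}\t{t.ref_allele or '-'}\t"
                f"{t.alt_allele or '-'}\t{t.variant_class}\t"
                f"{t.context or 'NA'}\t{t.effect or 'NA'}\t"
                f"{t.gene_id or 'NA'}\t{t.membership}\t"
                f"{int(t.engineered)}\n"
            )


def read_truth(path: str | Path) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                TruthRecord(
                    f[0], int(f[1]),
                    "" if f[2] == "-" else f[2],
                    "" if f[3] == "-" else f[3],
                    f[4],
                    None if f[5] == "NA" else f[5],
                    None if f[6] == "NA" else f[6],
                    None if f[7] == "NA" else f[7],
                    f[8], bool(int(f[9])),
                )
            )
    return out


def _models_to_gff(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.chrom, m.start)):
            gid, mid = m.gene_id, f"{m.gene_id}.1"
            fh.write(
                f"{m.chrom}\tpatchlift\tgene\t{m.start}\t{m.end}\t.\t"
                f"{m.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{m.chrom}\tpatchlift\tmRNA\t{m.start}\t{m.end}\t.\t"
                f"{m.strand}\t.\tID={mid};Parent={gid}\n"
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\tpatchlift\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"Parent={mid}\n"
                )
            # phase from cumulative CDS length in coding order
            ordered = m.cds if m.strand == "+" else list(reversed(m.cds))
            cum = 0
            phases = {}
            for s, e in ordered:
                phases[(s, e)] = (3 - cum % 3) % 3
                cum += e - s + 1
            for s, e in m.cds:
                fh.write(
                    f"{m.chrom}\tpatchlift\tCDS\t{s}\t{e}\t.\t{m.strand}\t"
                    f"{phases[(s, e)]}\tID={mid}.cds;Parent={mid}\n"
                )
            for s, e in m.utrs:
                # orient the UTR label by position relative to the CDS
                if m.strand == "+":
                    kind = "five_prime_UTR" if e < m.cds[0][0] else "three_prime_UTR"
                else:
                    kind = "five_prime_UTR" if s > m.cds[-1][1] else "three_prime_UTR"
                fh.write(
                    f"{m.chrom}\tpatchlift\t{kind}\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"Parent={mid}\n"
                )


def _write_go_annotation(
    rng: np.random.Generator, models: Sequence[GeneModel], path: str | Path
) -> None:
    terms = [f"GO:{7000000 + i:07d}" for i in range(30)]
    with open(path, "w") as fh:
        fh.write("gene\tterm\tnamespace\n")
        for m in models:
            k = int(rng.integers(1, 4))
            chosen = sorted(rng.choice(len(terms), size=k, replace=False))
            for t in chosen:
                fh.write(f"{m.gene_id}\t{terms[t]}\tmolecular_function\n")


def _aa_change_string(rng: np.random.Generator) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    a = aas[rng.integers(0, len(aas))]
    b = aas[rng.integers(0, len(aas))]
    return f"{a}{int(rng.integers(2, 500))}{b}"


def _write_scores(
    rng: np.random.Generator,
    models: Sequence[GeneModel],
    truth: Sequence[TruthRecord],
    path: str | Path,
    paper_shaped: bool,
) -> None:
    """Deleterious-score table.  The paper-shaped preset scores 386 genes
    and makes exactly 45 of them deleterious at the -2.5 cutoff."""
    rows: list[tuple[str, str, float]] = []
    if paper_shaped:
        gene_ids = sorted(m.gene_id for m in models)
        chosen = [gene_ids[i] for i in sorted(rng.permutation(len(gene_ids))[:386])]
        deleterious = set(
            chosen[i] for i in sorted(rng.permutation(386)[:45])
        )
        for gid in chosen:
            if gid in deleterious:
                score = float(rng.uniform(-8.0, -2.6))
            else:
                score = float(rng.uniform(-2.4, 0.0))
            rows.append((gid, _aa_change_string(rng), round(score, 3)))
    else:
        missense_genes = sorted(
            {t.gene_id for t in truth if t.effect == "missense" and t.gene_id}
        )
        for gid in missense_genes:
            rows.append(
                (gid, _aa_change_string(rng), round(float(rng.uniform(-6.0, 0.0)), 3))
            )
    with open(path, "w") as fh:
        fh.write("gene\tvariant\tscore\n")
        for gid, change, score in rows:
            fh.write(f"{gid}\t{change}\t{score}\n")


def _write_gene_classes(
    rng: np.random.Generator, models: Sequence[GeneModel], path: str | Path
) -> None:
    gene_ids = sorted(m.gene_id for m in models)
    perm = [gene_ids[i] for i in rng.permutation(len(gene_ids))]
    cursor = 0
    with open(path, "w") as fh:
        fh.write("gene_class\tgene\n")
        for cls_name, size in PAPER_SHAPED_CLASSES.items():
            members = sorted(perm[cursor : cursor + size])
            cursor += size
            for gid in members:
                fh.write(f"{cls_name}\t{gid}\n")


def write_fixture_bundle(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a self-contained bundle: reference FASTA, GFF3 annotation,
    two SDI variant sets, truth TSV, GO annotation TSV and score TSV
    (plus a gene-class TSV for the paper-shaped preset).  Byte-identical
    under identical seeds."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = simulate(config)
    rng = _rng(config, 3)
    paths = {
        "reference": out_dir / "reference.fasta",
        "annotation": out_dir / "annotation.gff3",
        "variants_a": out_dir / "variety_A.sdi",
        "variants_b": out_dir / "variety_B.sdi",
        "truth": out_dir / "truth.tsv",
        "go": out_dir / "go_annotation.tsv",
        "scores": out_dir / "scores.tsv",
    }
    write_fasta(bundle.reference, paths["reference"])
    _models_to_gff(bundle.models, paths["annotation"])
    write_sdi(bundle.variants_a, paths["variants_a"])
    write_sdi(bundle.variants_b, paths["variants_b"])
    write_truth(bundle.truth, paths["truth"])
    _write_go_annotation(rng, bundle.models, paths["go"])
    paper_shaped = config.preset == "paper-shaped"
    _write_scores(rng, bundle.models, bundle.truth, paths["scores"], paper_shaped)
    if paper_shaped:
        paths["gene_classes"] = out_dir / "gene_classes.tsv"
        _write_gene_classes(rng, bundle.models, paths["gene_classes"])
    with open(out_dir / "sim_config.json", "w") as fh:
        cfg = {
            k: (list(v) if isinstance(v, tuple) else
                dict(v) if isinstance(v, Mapping) else v)
            for k, v in vars(config).items()
        }
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
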