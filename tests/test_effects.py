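"""Context assignment, coding-effect calls and transfer status."""

import pandas as pd
import pytest

from patchlift.effects import (
    GeneIndex,
    TransferStatus,
    assign_context,
    call_deleterious,
    cds_effect,
    classify_effects,
    transfer_status,
    transfer_statuses,
)
from patchlift.genome import Genome
from patchlift.gff import GeneModel
from patchlift.sdi_io import VariantRecord

from oracles import translation_effect


def _single_exon_gene(cds: str, chrom_pad: int = 200) -> tuple[Genome, GeneModel]:
    """A plus-strand single-exon gene whose CDS is exactly ``cds``."""
    seq = "A" * chrom_pad + cds + "A" * chrom_pad
    genome = Genome([("c", seq)])
    start = chrom_pad + 1
    end = chrom_pad + len(cds)
    gene = GeneModel("g", "c", "+", exons=[(start, end)], cds=[(start, end)])
    return genome, gene


def _two_exon_gene() -> tuple[Genome, GeneModel]:
    """Plus-strand gene with UTRs and a GT..AG intron inside the CDS."""
    utr5 = "CCCCCCCCCC"                      # 10 bp
    cds_a = "ATGACTGGT"                      # M T G
    intron = "GT" + "A" * 50 + "AG"          # 54 bp
    cds_b = "AAATCCTAA"                      # K S *
    utr3 = "GGGGGGGGGG"
    seq = "T" * 100 + utr5 + cds_a + intron + cds_b + utr3 + "T" * 100
    genome = Genome([("c", seq)])
    e1 = (101, 100 + len(utr5) + len(cds_a))              # 101..119
    e2 = (e1[1] + len(intron) + 1, e1[1] + len(intron) + len(cds_b) + len(utr3))
    cds1 = (101 + len(utr5), e1[1])                        # 111..119
    cds2 = (e2[0], e2[0] + len(cds_b) - 1)
    gene = GeneModel(
        "g2", "c", "+",
        exons=[e1, e2],
        cds=[cds1, cds2],
        utrs=[(101, 110), (cds2[1] + 1, e2[1])],
    )
    return genome, gene


class TestAssignContext:
    @pytest.fixture
    def setup(self):
        genome, gene = _two_exon_gene()
        return genome, gene, GeneIndex([gene], window=5000)

    def test_far_variant_is_intergenic(self):
        _, gene = _two_exon_gene()
        index = GeneIndex([gene], window=5000)
        calls = assign_context(
            VariantRecord("c", gene.end + 10000, "A", "G"), index
        )
        assert calls == [("intergenic", None)]

    def test_cds_variant(self, setup):
        _, gene, index = setup
        assert assign_context(VariantRecord("c", 112, "T", "A"), index) == [
            ("CDS", "g2")
        ]

    def test_splice_site_at_intron_donor(self, setup):
        _, gene, index = setup
        (intron,) = gene.introns()
        for offset in (0, 1):
            calls = assign_context(
                VariantRecord("c", intron[0] + offset, "G", "C"), index
            )
            assert calls == [("splice_site", "g2")]
        # 3 bp into the intron is plain intronic
        calls = assign_context(
            VariantRecord("c", intron[0] + 2, "A", "C"), index
        )
        assert calls == [("intronic", "g2")]

    def test_utr_and_flanks_follow_strand(self, setup):
        _, gene, index = setup
        assert assign_context(VariantRecord("c", 105, "C", "T"), index) == [
            ("UTR", "g2")
        ]
        assert assign_context(VariantRecord("c", 50, "T", "A"), index) == [
            ("upstream", "g2")
        ]
        after = gene.end + 50
        assert assign_context(VariantRecord("c", after, "T", "A"), index) == [
            ("downstream", "g2")
        ]

    def test_minus_strand_swaps_upstream_downstream(self):
        gene = GeneModel("gm", "c", "-", exons=[(500, 900)], cds=[(500, 900)])
        index = GeneIndex([gene], window=5000)
        assert assign_context(VariantRecord("c", 100, "A", "G"), index) == [
            ("downstream", "gm")
        ]
        assert assign_context(VariantRecord("c", 1200, "A", "G"), index) == [
            ("upstream", "gm")
        ]


class TestCdsEffect:
    def test_missense_reports_amino_acid_change_at_codon_82(self):
        # codon 82 ACT (Thr); A->G makes GCT (Ala): "T82A"
        cds = "ATG" + "GCT" * 80 + "ACT" + "GCT" * 5 + "TAA"
        genome, gene = _single_exon_gene(cds)
        pos = gene.start + 81 * 3  # first base of codon 82
        call = cds_effect(VariantRecord("c", pos, "A", "G"), gene, genome)
        assert (call.effect, call.aa_change) == ("missense", "T82A")

    def test_third_position_leucine_wobble_is_synonymous(self):
        cds = "ATG" + "TTA" + "GCT" * 5 + "TAA"
        genome, gene = _single_exon_gene(cds)
        pos = gene.start + 5  # third base of codon 2 (TTA -> TTG, both Leu)
        call = cds_effect(VariantRecord("c", pos, "A", "G"), gene, genome)
        assert call.effect == "synonymous"
        assert call.aa_change is None

    def test_two_bp_deletion_is_frameshift(self):
        cds = "ATG" + "GCT" * 10 + "TAA"
        genome, gene = _single_exon_gene(cds)
        pos = gene.start + 9
        ref = genome.fetch("c", pos, pos + 1)
        call = cds_effect(VariantRecord("c", pos, ref, ""), gene, genome)
        assert call.effect == "frameshift"

    def test_three_bp_deletion_is_inframe(self):
        cds = "ATG" + "GCT" * 10 + "TAA"
        genome, gene = _single_exon_gene(cds)
        pos = gene.start + 9
        ref = genome.fetch("c", pos, pos + 2)
        call = cds_effect(VariantRecord("c", pos, ref, ""), gene, genome)
        assert call.effect == "inframe_indel"

    @pytest.mark.parametrize(
        "codon_idx,ref_base_offset,alt,expected",
        [
            (0, 0, "C", "start_lost"),    # ATG -> CTG
            (2, 2, "A", "stop_gained"),   # TAC -> TAA
        ],
    )
    def test_start_and_stop_alterations(
        self, codon_idx, ref_base_offset, alt, expected
    ):
        cds = "ATG" + "GCT" + "TAC" + "GCT" * 3 + "TAA"
        genome, gene = _single_exon_gene(cds)
        pos = gene.start + codon_idx * 3 + ref_base_offset
        ref = genome.fetch("c", pos, pos)
        call = cds_effect(VariantRecord("c", pos, ref, alt), gene, genome)
        assert call.effect == expected

    def test_stop_lost_at_terminal_codon(self):
        cds = "ATG" + "GCT" * 4 + "TAA"
        genome, gene = _single_exon_gene(cds)
        pos = gene.end - 1  # middle base of TAA -> TCA (Ser)
        call = cds_effect(VariantRecord("c", pos, "A", "C"), gene, genome)
        assert call.effect == "stop_lost"

    def test_agrees_with_translation_oracle_on_generated_cds_snvs(
        self, default_bundle
    ):
        b = default_bundle
        models = {m.gene_id: m for m in b.models}
        checked = 0
        for t in b.truth:
            if t.context != "CDS" or len(t.ref_allele) != 1 or len(t.alt_allele) != 1:
                continue
            if t.effect is None:  # ambiguous calls carry no truth effect
                continue
            gene = models[t.gene_id]
            variant = VariantRecord(t.chrom, t.pos, t.ref_allele, t.alt_allele)
            call = cds_effect(variant, gene, b.reference)
            assert call.effect == translation_effect(gene, variant, b.reference)
            assert call.effect == t.effect
            checked += 1
        assert checked >= 10

    def test_ambiguous_snv_gets_no_effect_call(self):
        cds = "ATG" + "GCT" * 5 + "TAA"
        genome, gene = _single_exon_gene(cds)
        calls = classify_effects(
            [VariantRecord("c", gene.start + 4, "C", "Y")], [gene], genome
        )
        (call,) = calls
        assert call.context == "CDS"
        assert call.effect == "none"
        assert call.ambiguous


class TestTransferStatus:
    def _call(self, effect, context="CDS"):
        v = VariantRecord("c", 10, "A", "G")
        from patchlift.effects import EffectCall

        return EffectCall(v, "g", context, effect)

    def test_benign_calls_transfer_intact(self):
        calls = [self._call("synonymous"), self._call("missense")]
        assert transfer_status(calls) is TransferStatus.TRANSFERRED

    def test_splice_damage_alone_alters_structure(self):
        calls = [self._call("splice_disrupted", "splice_site")]
        assert transfer_status(calls) is TransferStatus.ALTERED_STRUCTURE

    @pytest.mark.parametrize(
        "effect", ["frameshift", "start_lost", "stop_lost", "stop_gained"]
    )
    def test_disruption_dominates_everything(self, effect):
        calls = [
            self._call("splice_disrupted", "splice_site"),
            self._call(effect),
        ]
        assert transfer_status(calls) is TransferStatus.NOT_TRANSFERRED

    def test_untouched_gene_is_transferred(self):
        assert transfer_status([]) is TransferStatus.TRANSFERRED

    def test_monotone_adding_damage_never_improves(self):
        rank = {
            TransferStatus.TRANSFERRED: 0,
            TransferStatus.ALTERED_STRUCTURE: 1,
            TransferStatus.NOT_TRANSFERRED: 2,
        }
        base = [self._call("missense")]
        for extra in ("splice_disrupted", "frameshift", "stop_gained"):
            context = "splice_site" if extra == "splice_disrupted" else "CDS"
            assert (
                rank[transfer_status(base + [self._call(extra, context)])]
                >= rank[transfer_status(base)]
            )

    def test_statuses_recover_engineered_truth(self, default_bundle):
        b = default_bundle
        union = sorted(
            {r for r in b.variants_a + b.variants_b},
            key=lambda r: (r.chrom, r.pos),
        )
        calls = classify_effects(union, b.models, b.reference)
        statuses = transfer_statuses(calls, b.models)
        disrupting = {"frameshift", "start_lost", "stop_lost", "stop_gained"}
        for t in b.truth:
            if not t.engineered:
                continue
            if t.effect in disrupting:
                assert statuses[t.gene_id] is TransferStatus.NOT_TRANSFERRED


class TestCallDeleterious:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "variant", "score"])

    def test_threshold_is_inclusive_below(self):
        table = self._table(
            [("g1", "T82A", -4.0), ("g2", "K9R", -1.0), ("g3", "P5L", -2.5)]
        )
        out, summary = call_deleterious(table)
        assert out["deleterious"].tolist() == [True, False, True]
        assert summary["n_deleterious_genes"] == 2

    def test_gene_level_fraction_counts_genes_once(self):
        rows = [(f"g{i}", "A1V", -1.0) for i in range(341)]
        rows += [(f"d{i}", "A1V", -3.0) for i in range(45)]
        rows += [("d0", "C2W", -5.0)]  # second variant of an already-hit gene
        out, summary = call_deleterious(self._table(rows))
        assert summary["n_genes"] == 386
        assert summary["n_deleterious_genes"] == 45
        assert summary["fraction"] == pytest.approx(45 / 386)
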