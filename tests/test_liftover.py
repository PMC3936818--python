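"""Coordinate lifting and GFF3 annotation transfer."""

import numpy as np
import pytest

from patchlift.genome import Genome
from patchlift.gff import read_gff
from patchlift.liftover import lift_annotation, lift_position
from patchlift.offsets import DELETED, LiftPolicy, OffsetMap
from patchlift.reconstruct import apply_variants
from patchlift.sdi_io import VariantRecord

from oracles import base_tracking_map


def _map_for(ref_seq: str, records):
    genome = Genome([("c", ref_seq)])
    _, offset_map = apply_variants(genome, records)
    return offset_map


class TestLiftPosition:
    def test_zero_delta_map_is_identity(self):
        offset_map = _map_for("A" * 1000, [])
        assert lift_position(offset_map, "c", 500) == 500

    def test_insertion_shifts_only_downstream(self):
        offset_map = _map_for("A" * 50, [VariantRecord("c", 10, "", "GGG")])
        assert lift_position(offset_map, "c", 10) == 10
        assert lift_position(offset_map, "c", 11) == 14

    def test_deleted_position_clamps_to_last_surviving_base(self):
        ref = "A" * 19 + "C" * 10 + "A" * 21
        offset_map = _map_for(ref, [VariantRecord("c", 20, "C" * 10, "")])
        assert lift_position(offset_map, "c", 25, policy="clamp") == 19
        assert lift_position(offset_map, "c", 25) is DELETED
        assert lift_position(offset_map, "c", 30) == 20

    def test_unknown_chromosome_and_out_of_range(self):
        offset_map = _map_for("A" * 10, [])
        from patchlift.errors import CoordinateError

        with pytest.raises(CoordinateError):
            lift_position(offset_map, "nope", 1)
        with pytest.raises(CoordinateError):
            lift_position(offset_map, "c", 11)

    def test_matches_base_tracking_oracle_on_random_maps(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            length = int(rng.integers(200, 1500))
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
            genome = Genome([("c", seq)])
            records = _random_records(rng, seq)
            _, offset_map = apply_variants(genome, records)
            dest = base_tracking_map(length, records)
            for pos in range(1, length + 1):
                got = offset_map.lift("c", pos, LiftPolicy.REJECT)
                want = dest.get(pos)
                if want is None:
                    assert got is DELETED, (pos, records)
                else:
                    assert got == want, (pos, records)

    def test_monotone_on_surviving_positions(self, default_bundle):
        b = default_bundle
        _, offset_map = apply_variants(b.reference, b.variants_a)
        for name in b.reference.names:
            prev = 0
            for pos in range(1, b.reference.length(name) + 1, 97):
                out = offset_map.lift(name, pos)
                if out is DELETED:
                    continue
                assert out > prev
                prev = out


def _random_records(rng, seq, n_max=40):
    """Non-overlapping random edits with a 1 bp separation guard."""
    length = len(seq)
    blocked = np.zeros(length + 3, dtype=bool)
    records = []
    for _ in range(n_max):
        kind = int(rng.integers(0, 4))
        if kind == 0:
            pos = int(rng.integers(1, length + 1))
            if blocked[pos - 1 : pos + 2].any():
                continue
            ref = seq[pos - 1]
            records.append(
                VariantRecord("c", pos, ref, "ACGT".replace(ref, "")[0])
            )
            blocked[max(0, pos - 2) : pos + 2] = True
        elif kind == 1:
            pos = int(rng.integers(1, length))
            if blocked[pos - 1 : pos + 3].any():
                continue
            alt = "".join(
                np.array(list("ACGT"))[rng.integers(0, 4, int(rng.integers(1, 7)))]
            )
            records.append(VariantRecord("c", pos, "", alt))
            blocked[max(0, pos - 2) : pos + 3] = True
        elif kind == 2:
            size = int(rng.integers(1, 9))
            pos = int(rng.integers(2, max(3, length - size)))
            if blocked[pos - 1 : pos + size + 2].any():
                continue
            records.append(VariantRecord("c", pos, seq[pos - 1 : pos - 1 + size], ""))
            blocked[max(0, pos - 2) : pos + size + 2] = True
        else:
            r, a = int(rng.integers(1, 4)), int(rng.integers(1, 6))
            if r == a:
                continue
            pos = int(rng.integers(2, max(3, length - r)))
            if blocked[pos - 1 : pos + r + 2].any():
                continue
            alt = "".join(np.array(list("ACGT"))[rng.integers(0, 4, a)])
            ref = seq[pos - 1 : pos - 1 + r]
            if alt[: min(r, a)] == ref[: min(r, a)]:
                continue
            records.append(VariantRecord("c", pos, ref, alt))
            blocked[max(0, pos - 2) : pos + r + 2] = True
    return sorted(records, key=lambda x: x.pos)


GFF_TEXT = """\
##gff-version 3
c\tsrc\tgene\t101\t700\t.\t+\t.\tID=g1
c\tsrc\tmRNA\t101\t700\t.\t+\t.\tID=m1;Parent=g1
c\tsrc\texon\t101\t300\t.\t+\t.\tID=e1;Parent=m1
c\tsrc\texon\t501\t700\t.\t+\t.\tID=e2;Parent=m1
c\tsrc\tCDS\t151\t300\t.\t+\t0\tID=c1;Parent=m1
c\tsrc\tCDS\t501\t650\t.\t+\t0\tID=c2;Parent=m1
"""


@pytest.fixture
def gff_path(tmp_path):
    path = tmp_path / "in.gff3"
    path.write_text(GFF_TEXT)
    return path


class TestLiftAnnotation:
    def test_zero_delta_map_preserves_every_feature(self, gff_path):
        offset_map = _map_for("A" * 1000, [])
        features = read_gff(gff_path)
        lifted, report = lift_annotation(features, offset_map)
        assert [(f.start, f.end) for f in lifted] == [
            (f.start, f.end) for f in features
        ]
        assert all(e.status == "lifted" for e in report)

    def test_intronic_insertion_stretches_gene_and_shifts_downstream_exon(
        self, gff_path
    ):
        # 300 bp inserted inside the intron (after base 400)
        offset_map = _map_for(
            "A" * 1000, [VariantRecord("c", 400, "", "G" * 300)]
        )
        lifted, report = lift_annotation(read_gff(gff_path), offset_map)
        by_id = {f.attributes["ID"][0]: f for f in lifted}
        gene = by_id["g1"]
        assert gene.end - gene.start == 700 - 101 + 300
        assert (by_id["e1"].start, by_id["e1"].end) == (101, 300)
        assert (by_id["e2"].start, by_id["e2"].end) == (801, 1000)
        assert all(e.status == "lifted" for e in report)

    def test_exon_inside_deletion_dropped_and_parents_truncated(self, gff_path):
        ref = "A" * 480 + "C" * 240 + "A" * 280
        offset_map = _map_for(
            ref, [VariantRecord("c", 481, "C" * 240, "")]
        )
        lifted, report = lift_annotation(read_gff(gff_path), offset_map)
        by_status = {e.feature_id: e.status for e in report}
        assert by_status["e2"] == "dropped"
        assert by_status["c2"] == "dropped"
        assert by_status["m1"] == "truncated"
        ids = [f.attributes["ID"][0] for f in lifted]
        assert "e2" not in ids and "e1" in ids

    def test_endpoint_in_deletion_clamped_and_flagged(self, gff_path):
        # deletion spanning the end of exon2 (601..720)
        ref = "A" * 600 + "C" * 120 + "A" * 280
        offset_map = _map_for(
            ref, [VariantRecord("c", 601, "C" * 120, "")]
        )
        lifted, report = lift_annotation(read_gff(gff_path), offset_map)
        by_id = {f.attributes["ID"][0]: f for f in lifted}
        entry = {e.feature_id: e for e in report}["e2"]
        assert entry.status == "truncated"
        assert by_id["e2"].end == 600  # last surviving base
        assert by_id["g1"].end == 600

    def test_phase_recomputed_from_lifted_cds_lengths(self, gff_path):
        # 1 bp deleted from the first CDS piece: second piece phase shifts
        ref = "A" * 1000
        offset_map = _map_for(ref, [VariantRecord("c", 200, "A", "")])
        lifted, _ = lift_annotation(read_gff(gff_path), offset_map)
        cds = [f for f in lifted if f.featuretype == "CDS"]
        first, second = sorted(cds, key=lambda f: f.start)
        assert first.frame == "0"
        # first piece is now 149 bp; 149 % 3 == 2, so 1 base to skip
        assert second.frame == "1"

    def test_unknown_chromosome_reported_not_fatal(self, tmp_path):
        path = tmp_path / "x.gff3"
        path.write_text("##gff-version 3\nzz\tsrc\tgene\t1\t10\t.\t+\t.\tID=g9\n")
        offset_map = _map_for("A" * 100, [])
        lifted, report = lift_annotation(read_gff(path), offset_map)
        assert lifted == []
        assert report[0].status == "unmapped_chrom"


class TestChainRoundTrip:
    def test_lift_semantics_preserved_through_chain_file(self, tmp_path):
        rng = np.random.default_rng(3)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 800)])
        records = _random_records(rng, seq)
        _, offset_map = apply_variants(Genome([("c", seq)]), records)
        path = tmp_path / "map.chain"
        offset_map.write_chain(path)
        reread = OffsetMap.read_chain(path)
        for pos in range(1, 801):
            assert reread.lift("c", pos) == offset_map.lift("c", pos)
            assert reread.lift("c", pos, LiftPolicy.CLAMP) == offset_map.lift(
                "c", pos, LiftPolicy.CLAMP
            )
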