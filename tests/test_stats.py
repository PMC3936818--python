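"""Variant accounting, shared/specific partitions, depth, N50 and
gene-class tables."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from patchlift.effects import EffectCall, TransferStatus
from patchlift.errors import ValidationError
from patchlift.sdi_io import VariantRecord
from patchlift.stats import (
    complement_segments,
    expected_depth,
    feature_breakdown,
    gene_class_table,
    n50,
    n50_between,
    polymorphic_regions,
    round_half_up,
    shared_fraction,
    shared_specific,
    transfer_summary,
    validation_concordance,
    variant_class_counts,
    with_total_row,
)

from oracles import n50_bruteforce


class TestVariantClassCounts:
    def test_empty_set_is_all_zeros(self):
        table = variant_class_counts([])
        assert (table["count"] == 0).all()

    def test_counts_match_generator_truth(self, default_bundle):
        b = default_bundle
        truth_classes = Counter(
            t.variant_class for t in b.truth if t.membership in ("A", "both")
        )
        table = variant_class_counts(b.variants_a)
        for cls, n in truth_classes.items():
            assert table.loc[cls, "count"] == n
        assert table.loc["Total", "count"] == len(b.variants_a)

    def test_total_row_sums_classes(self, default_bundle):
        table = variant_class_counts(default_bundle.variants_b)
        body = table.drop(index="Total")
        assert table.loc["Total"].equals(body.sum())

    def test_ambiguous_excluded_column(self):
        records = [
            VariantRecord("c", 1, "A", "G"),
            VariantRecord("c", 5, "A", "R"),
        ]
        table = variant_class_counts(records)
        assert table.loc["SNP", "count"] == 2
        assert table.loc["SNP", "count_excluding_ambiguous"] == 1


class TestFeatureBreakdown:
    def _call(self, pos, context, gene=None, ref="A", alt="G"):
        return EffectCall(
            VariantRecord("c", pos, ref, alt), gene, context,
            "none" if context not in ("CDS",) else "missense",
        )

    def test_all_intergenic_fixture_has_zero_gene_counts(self):
        calls = [self._call(i * 10, "intergenic") for i in range(1, 6)]
        table = feature_breakdown(calls)
        total = table[table.stratum == "total"].set_index("feature")
        assert total.loc["intergenic", "variants"] == 5
        assert (total["genes"] == 0).all()

    def test_feature_counts_sum_to_variant_count(self, default_bundle):
        from patchlift.effects import classify_effects

        b = default_bundle
        calls = classify_effects(b.variants_a, b.models, b.reference)
        table = feature_breakdown(calls)
        total = table[table.stratum == "total"]
        assert total["variants"].sum() == len(b.variants_a)

    def test_length_strata_from_known_composition(self):
        calls = []
        pos = 100
        for length in [1, 2, 5, 6, 50, 101, 500]:
            calls.append(
                EffectCall(
                    VariantRecord("c", pos, "A" * length, ""), None, "intergenic"
                )
            )
            pos += 1000
        table = feature_breakdown(calls).set_index(["stratum", "feature"])
        assert table.loc[("total", "intergenic"), "variants"] == 7
        assert table.loc[("lt6", "intergenic"), "variants"] == 3
        assert table.loc[("gt100", "intergenic"), "variants"] == 2


class TestSharedSpecific:
    def test_identical_sets_fully_shared(self):
        records = [VariantRecord("c", i * 5, "A", "G") for i in range(1, 9)]
        common, a_only, b_only = shared_specific(records, list(records))
        assert common == records and a_only == [] and b_only == []

    def test_disjoint_sets_share_nothing(self):
        a = [VariantRecord("c", 10, "A", "G")]
        b = [VariantRecord("c", 20, "A", "G")]
        common, a_only, b_only = shared_specific(a, b)
        assert common == [] and a_only == a and b_only == b

    def test_partition_is_exact(self, default_bundle):
        b = default_bundle
        common, a_only, b_only = shared_specific(b.variants_a, b.variants_b)
        assert len(common) + len(a_only) == len(b.variants_a)
        assert len(common) + len(b_only) == len(b.variants_b)
        truth_both = sum(1 for t in b.truth if t.membership == "both")
        assert len(common) == truth_both

    def test_shared_fraction_half_up_rounding(self):
        assert shared_fraction(55_668, 75_984) == 73.3
        assert shared_fraction(25_208, 46_433) == 54.3
        assert shared_fraction(0, 100) == 0.0
        with pytest.raises(ValidationError):
            shared_fraction(1, 0)


class TestExpectedDepth:
    def test_published_read_counts_reproduce_fold_coverage(self):
        assert expected_depth(155_751_012, 100, 900_000_000) == 34.6
        assert expected_depth(177_758_218, 100, 900_000_000) == 39.5

    def test_tiny_example(self):
        assert expected_depth(1, 100, 200) == 1.0

    def test_zero_genome_size_rejected(self):
        with pytest.raises(ValidationError):
            expected_depth(1, 100, 0)


class TestPolymorphicRegionsAndN50:
    def test_no_variants_leaves_whole_chromosomes(self):
        segments = complement_segments({}, {"c1": 100, "c2": 60})
        assert sorted(segments) == [60, 100]

    def test_example_segment_set(self):
        # total 18, half 9: segments >= 8 cover only 8, segments >= 4
        # cover 16, so the N50 is 4
        assert n50([8, 4, 4, 2]) == 4
        assert n50([8, 4, 4, 2]) == n50_bruteforce([8, 4, 4, 2])

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(300):
            k = int(rng.integers(1, 21))
            lengths = rng.integers(1, 1000, size=k).tolist()
            assert n50(lengths) == n50_bruteforce(lengths)

    def test_cluster_merging_matches_constructed_truth(self):
        # three clusters separated by > merge_gap
        records = []
        for base in (1000, 5000, 9000):
            for offset in (0, 30, 60):
                records.append(VariantRecord("c", base + offset, "A", "G"))
        regions = polymorphic_regions(records, merge_gap=100)
        assert len(regions["c"]) == 3
        segments = complement_segments(regions, {"c": 12_000})
        assert len(segments) == 4
        assert n50_between(records, {"c": 12_000}, merge_gap=100) == n50(segments)

    def test_deletion_footprint_extends_region(self):
        records = [VariantRecord("c", 11, "A" * 30, "")]
        regions = polymorphic_regions(records, merge_gap=0)
        assert regions["c"] == [(11, 40)]


class TestTransferSummary:
    def test_published_not_transferred_percentage(self):
        statuses = {
            f"g{i}": TransferStatus.NOT_TRANSFERRED for i in range(606)
        }
        table = transfer_summary(statuses, total_annotations=34_727)
        assert table.loc["not_transferred", "percent"] == 1.7

    def test_no_failures_is_all_transferred(self):
        table = transfer_summary({}, total_annotations=120)
        assert table.loc["transferred", "count"] == 120
        assert table.loc["transferred", "percent"] == 100.0

    def test_engineered_fraction_from_counts(self):
        statuses = {f"g{i}": TransferStatus.NOT_TRANSFERRED for i in range(10)}
        table = transfer_summary(statuses, total_annotations=200)
        assert table.loc["not_transferred", "percent"] == 5.0

    def test_total_smaller_than_damage_rejected(self):
        statuses = {f"g{i}": TransferStatus.NOT_TRANSFERRED for i in range(10)}
        with pytest.raises(ValidationError):
            transfer_summary(statuses, total_annotations=5)


class TestValidationConcordance:
    def _evidence(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "alt", "depth"])

    def test_identical_sets_fully_validated(self):
        snps = [VariantRecord("c", i, "A", "G") for i in (5, 10, 15)]
        evidence = self._evidence([("c", i, "G", 10) for i in (5, 10, 15)])
        assert validation_concordance(snps, evidence) == 1.0

    def test_no_site_reaching_depth_is_na(self):
        snps = [VariantRecord("c", 5, "A", "G")]
        evidence = self._evidence([("c", 5, "G", 3)])
        assert validation_concordance(snps, evidence, min_depth=6) is None

    def test_recovers_constructed_concordance_rate(self):
        rng = np.random.default_rng(9)
        snps = []
        rows = []
        n = 2000
        for i in range(n):
            pos = 10 * (i + 1)
            snps.append(VariantRecord("c", pos, "A", "G"))
            alt = "G" if rng.random() < 0.9 else "T"
            rows.append(("c", pos, alt, int(rng.integers(6, 30))))
        frac = validation_concordance(snps, self._evidence(rows))
        se = (0.9 * 0.1 / n) ** 0.5
        assert abs(frac - 0.9) < 3 * se


class TestGeneClassTable:
    def _calls(self, spec):
        """spec: list of (gene, n_variants)"""
        calls = []
        pos = 100
        for gene, n in spec:
            for _ in range(n):
                calls.append(
                    EffectCall(
                        VariantRecord("c", pos, "A", "G"), gene, "intronic"
                    )
                )
                pos += 10
        return calls

    def test_counts_percentages_and_common_specific(self):
        classes = {"alpha": ["g1", "g2", "g3", "g4"], "beta": ["g5", "g6"]}
        calls_a = self._calls([("g1", 3), ("g2", 1), ("g5", 2)])
        calls_b = self._calls([("g1", 2), ("g6", 4)])
        table = gene_class_table(
            classes, {"A": calls_a, "B": calls_b},
            annotated_genes={f"g{i}" for i in range(1, 7)},
        )
        assert table.loc["alpha", "A_polymorphic"] == 2
        assert table.loc["alpha", "A_polymorphic_pct"] == 50.0
        assert table.loc["alpha", "A_variants"] == 4
        assert table.loc["alpha", "common"] == 1        # g1 in both
        assert table.loc["beta", "A_specific"] == 1     # g5
        assert table.loc["beta", "B_specific"] == 1     # g6
        assert table.loc["Total", "common"] == 1
        assert table.loc["Total", "A_polymorphic"] == 3

    def test_unknown_class_member_warned_and_excluded(self):
        classes = {"alpha": ["g1", "ghost"]}
        with pytest.warns(UserWarning, match="absent"):
            table = gene_class_table(
                classes, {"A": [], "B": []}, annotated_genes={"g1"}
            )
        assert table.loc["alpha", "genes"] == 1

    def test_class_with_no_variants(self):
        classes = {"alpha": ["g1"]}
        table = gene_class_table(
            classes, {"A": [], "B": []}, annotated_genes={"g1"}
        )
        assert table.loc["alpha", "A_polymorphic"] == 0
        assert table.loc["alpha", "A_polymorphic_pct"] == 0.0


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected", [(71.45, 71.5), (73.25, 73.3), (1.744, 1.7), (2.05, 2.1)]
    )
    def test_half_up(self, value, expected):
        assert round_half_up(value, 1) == expected

    def test_with_total_row_sums_numeric_columns(self):
        df = pd.DataFrame({"n": [1, 2, 3]}, index=list("abc"))
        out = with_total_row(df)
        assert out.loc["Total", "n"] == 6
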