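"""Haplotype classification, precedence rules, and frequency tables."""

import numpy as np
import pandas as pd
import pytest

import sd1hap as s
from sd1hap.classify import ClassificationConflict, reciprocal_overlap
from sd1hap.deletions import DeletionCall
from sd1hap.variant_io import GenotypeCall, VariantRecord

SITE_100 = 38_382_764
SITE_340 = 38_385_057


def _hom(pos, ref, alt, sample="acc"):
    return VariantRecord(
        "chr01", pos, ref, [alt], {sample: GenotypeCall(sample, (1, 1), 30, 1.0)}
    )


def _het(pos, ref, alt, sample="acc"):
    return VariantRecord(
        "chr01", pos, ref, [alt], {sample: GenotypeCall(sample, (0, 1), 30, 0.5)}
    )


def _del_call(start, end):
    return DeletionCall("chr01", start, end, support=10, size_estimate=end - start + 1)


class TestDeletionGeometry:
    def test_published_lengths_and_3p_distance(self, definitions):
        geom = s.deletion_geometry(definitions)
        assert geom["lengths"][7] == 383
        assert geom["lengths"][6] == 1279
        assert geom["pairwise_3p_distances"][(6, 7)] == 13

    def test_3p_convention_invariance(self, definitions):
        """Using end instead of end+1 gives the same pairwise distance."""
        d6 = definitions[6].interval
        d7 = definitions[7].interval
        assert abs(d6[1] - d7[1]) == abs((d6[1] + 1) - (d7[1] + 1)) == 13

    def test_non_deletion_type_rejected(self, definitions):
        with pytest.raises(ValueError):
            definitions[1].interval


class TestClassifyAccession:
    def test_structural_type7_from_deletion_call(self, definitions):
        call = s.classify_accession(
            [], [_del_call(38_382_755, 38_383_144)], definitions, "acc"
        )
        assert call.label == 7

    def test_overlap_below_threshold_not_matched(self, definitions):
        call = s.classify_accession(
            [], [_del_call(38_382_762, 38_383_600)], definitions, "acc"
        )
        assert call.label == 1

    def test_conflicting_structural_matches_raise(self, definitions):
        with pytest.raises(ClassificationConflict):
            s.classify_accession(
                [],
                [_del_call(38_382_762, 38_383_144), _del_call(38_381_879, 38_383_157)],
                definitions,
                "acc",
            )

    def test_empty_variants_is_wild_type(self, definitions):
        call = s.classify_accession([], [], definitions, "acc")
        assert call.label == 1 and call.zygosity == "hom"

    def test_er_combination_is_type11(self, definitions):
        call = s.classify_accession([_hom(SITE_100, "G", "A")], [], definitions, "acc")
        assert call.label == 11

    def test_eq_combination_is_type2(self, definitions):
        recs = [_hom(SITE_100, "G", "A"), _hom(SITE_340, "G", "A")]
        assert s.classify_accession(recs, [], definitions, "acc").label == 2

    def test_gq_combination_gets_explicit_label(self, definitions):
        call = s.classify_accession([_hom(SITE_340, "G", "A")], [], definitions, "acc")
        assert call.label == "GQ_unobserved"

    def test_point_lof_precedes_combo(self, definitions):
        """A homozygous stop at residue 342 wins over readable 100/340 states."""
        recs = [
            _hom(38_385_064, "C", "A"),  # Tyr342*
            _hom(SITE_100, "G", "A"),
            _hom(SITE_340, "G", "A"),
        ]
        assert s.classify_accession(recs, [], definitions, "acc").label == 8

    def test_structural_precedes_point(self, definitions):
        recs = [_hom(38_385_064, "C", "A")]
        call = s.classify_accession(
            recs, [_del_call(38_382_762, 38_383_144)], definitions, "acc"
        )
        assert call.label == 7

    def test_het_at_deciding_site_is_heterozygous(self, definitions):
        call = s.classify_accession([_het(SITE_100, "G", "A")], [], definitions, "acc")
        assert call.label == "heterozygous" and call.zygosity == "het"

    def test_het_allowed_when_not_homozygous_only(self, definitions):
        call = s.classify_accession(
            [_het(SITE_100, "G", "A")], [], definitions, "acc", homozygous_only=False
        )
        assert call.label == 11 and call.zygosity == "het"

    def test_order_independence(self, definitions, rng):
        recs = [
            _hom(38_385_064, "C", "A"),
            _hom(SITE_100, "G", "A"),
            _hom(SITE_340, "G", "A"),
        ]
        labels = set()
        for _ in range(10):
            perm = [recs[i] for i in rng.permutation(len(recs))]
            labels.add(s.classify_accession(perm, [], definitions, "acc").label)
        assert labels == {8}

    def test_indel_diagnostic(self, definitions, reference):
        # 2-bp deletion at the type 9 interval, anchored one base left
        pos = 38_382_845
        rec = VariantRecord(
            "chr01", pos, "ATT", ["A"],
            {"acc": GenotypeCall("acc", (1, 1), 30, 1.0)},
        )
        assert s.classify_accession([rec], [], definitions, "acc").label == 9


class TestPerfectRecovery:
    def test_noiseless_cohort_recovers_all_labels(self, small_cohort):
        recs = s.filter_variants(small_cohort.variants)
        calls_by = {}
        for acc in small_cohort.accessions:
            pairs = small_cohort.pairs_for(acc)
            calls_by[acc] = s.detect_deletions(pairs, s.fit_insert_model(pairs))
        calls = s.classify_cohort(
            recs, calls_by, small_cohort.definitions, samples=small_cohort.accessions
        )
        for call in calls:
            assert call.label == small_cohort.truth.label(call.accession)


class TestFrequencyTable:
    def _meta(self, accs, subpop="indica", category="landrace"):
        return pd.DataFrame(
            {"accession": accs, "subpopulation": subpop, "category": category}
        )

    def test_single_class_single_subpop(self):
        calls = [s.HaplotypeCall(f"a{i}", 1) for i in range(10)]
        table = s.tabulate_frequencies(calls, self._meta([f"a{i}" for i in range(10)]))
        assert table.counts.loc["1", "indica"] == 10
        assert table.percent.loc["1", "indica"] == 100.0

    def test_heterozygous_excluded_from_denominator(self):
        calls = [s.HaplotypeCall("a", 1), s.HaplotypeCall("b", 2),
                 s.HaplotypeCall("c", "heterozygous", zygosity="het")]
        table = s.tabulate_frequencies(calls, self._meta(["a", "b", "c"]))
        assert table.column_totals["indica"] == 2
        assert "heterozygous" not in table.counts.index

    def test_counts_match_truth_exactly(self, small_cohort):
        truth = small_cohort.truth
        calls = [
            s.HaplotypeCall(a, truth.label(a),
                            zygosity="het" if truth.label(a) == "heterozygous" else "hom")
            for a in small_cohort.accessions
        ]
        table = s.tabulate_frequencies(calls, small_cohort.metadata)
        for label in table.counts.index:
            expected = sum(
                1 for a in small_cohort.accessions if str(truth.label(a)) == label
            )
            assert table.counts.loc[label].sum() == expected

    def test_missing_metadata_reported_and_excluded(self):
        calls = [s.HaplotypeCall("a", 1), s.HaplotypeCall("ghost", 1)]
        table = s.tabulate_frequencies(calls, self._meta(["a"]))
        assert table.excluded == ["ghost"]
        assert table.counts.values.sum() == 1

    def test_percentages_sum_to_100(self, small_cohort):
        truth = small_cohort.truth
        calls = [s.HaplotypeCall(a, truth.label(a)) for a in small_cohort.accessions
                 if truth.label(a) != "heterozygous"]
        table = s.tabulate_frequencies(calls, small_cohort.metadata)
        for col in table.percent.columns:
            assert table.percent[col].sum() == pytest.approx(100.0, abs=0.5)

    def test_marginals_invariant_under_permutation(self, small_cohort):
        truth = small_cohort.truth
        calls = [s.HaplotypeCall(a, truth.label(a)) for a in small_cohort.accessions]
        t1 = s.tabulate_frequencies(calls, small_cohort.metadata)
        t2 = s.tabulate_frequencies(list(reversed(calls)), small_cohort.metadata)
        assert t1.counts.sort_index().equals(t2.counts.sort_index())


class TestReciprocalOverlap:
    @pytest.mark.parametrize("a,b,expected", [
        ((1, 100), (1, 100), 1.0),
        ((1, 100), (51, 150), 0.5),
        ((1, 100), (200, 300), 0.0),
        ((1, 1000), (1, 100), 0.1),
    ])
    def test_values(self, a, b, expected):
        assert reciprocal_overlap(a, b) == pytest.approx(expected)
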