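"""Substitution classification, Ti/Tv, oncoplot matrix, rainfall, demographics."""

from fractions import Fraction

import numpy as np
import pytest

from corticophylo.cohort_io import SampleVariantSet
from corticophylo.mutation_summary import (
    SNV_CLASSES,
    classify_snv,
    cohort_demographics,
    gene_sample_matrix,
    rainfall,
    titv_summary,
    variant_spectrum,
)

from conftest import make_variant

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
ALL_SUBS = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]


class TestClassifySnv:
    @pytest.mark.parametrize(
        "ref,alt,value,is_ti",
        [
            ("C", "T", "C>T", True),
            ("G", "A", "C>T", True),  # purine frame folds onto the pyrimidine class
            ("T", "C", "T>C", True),
            ("A", "G", "T>C", True),
            ("C", "G", "C>G", False),
            ("C", "A", "C>A", False),
            ("G", "T", "C>A", False),
        ],
    )
    def test_classification(self, ref, alt, value, is_ti):
        cls = classify_snv(ref, alt)
        assert cls.value == value and cls.is_transition == is_ti

    @pytest.mark.parametrize("ref,alt", ALL_SUBS)
    def test_strand_complement_symmetry(self, ref, alt):
        assert classify_snv(ref, alt) == classify_snv(_COMPLEMENT[ref], _COMPLEMENT[alt])

    def test_exactly_two_transition_classes(self):
        ti = {c for c in SNV_CLASSES if classify_snv(c[0], c[2]).is_transition}
        assert ti == {"C>T", "T>C"}

    @pytest.mark.parametrize("ref,alt", [("C", "C"), ("N", "T"), ("C", "U")])
    def test_invalid_substitutions_rejected(self, ref, alt):
        with pytest.raises(ValueError):
            classify_snv(ref, alt)


class TestTitv:
    def test_counts_and_fraction(self):
        recs = [
            make_variant("v1", ref="C", alt="T"),
            make_variant("v2", ref="T", alt="C"),
            make_variant("v3", ref="C", alt="G"),
        ]
        ti, tv, frac = titv_summary(recs)
        assert (ti, tv) == (2, 1)
        assert frac == pytest.approx(2 / 3)

    def test_empty_input_flagged_undefined(self):
        ti, tv, frac = titv_summary([])
        assert (ti, tv, frac) == (0, 0, None)

    def test_non_snps_ignored_and_total_conserved(self):
        recs = [
            make_variant("v1", ref="C", alt="T"),
            make_variant("v2", ref="CAT", alt="C", vclass="frameshift_del"),
        ]
        ti, tv, _ = titv_summary(recs)
        assert ti + tv == 1


class TestGeneSampleMatrix:
    def test_published_carrier_counts(self, cohort):
        gm = gene_sample_matrix(
            cohort, ("USP8", "TP53", "AURKA", "EGFR", "HSD3B1", "CDKN1A")
        )
        assert gm.carrier_counts() == {
            "HSD3B1": 10, "TP53": 9, "CDKN1A": 6, "EGFR": 6, "AURKA": 4, "USP8": 2
        }
        # rows sorted by descending carrier count, ties by panel order
        assert gm.genes == ["HSD3B1", "TP53", "EGFR", "CDKN1A", "AURKA", "USP8"]

    def test_counts_invariant_under_sample_reordering(self, cohort):
        from corticophylo.cohort_io import CohortTable

        rev = CohortTable(tumors=list(reversed(cohort.tumors)))
        a = gene_sample_matrix(cohort, ("TP53", "USP8")).carrier_counts()
        b = gene_sample_matrix(rev, ("TP53", "USP8")).carrier_counts()
        assert a == b

    def test_empty_panel_degenerate(self, cohort):
        gm = gene_sample_matrix(cohort, ())
        assert gm.genes == [] and gm.present.size == 0

    def test_absent_gene_retained_with_zero_row(self, cohort):
        gm = gene_sample_matrix(cohort, ("BRAF",))
        assert gm.carrier_counts() == {"BRAF": 0}


class TestRainfall:
    def _sample(self, positions, chrom="chr1"):
        recs = [
            make_variant(f"{chrom}:{p}:C>T", chrom=chrom, pos=p) for p in positions
        ]
        return SampleVariantSet("s", recs)

    def test_planted_kataegis_cluster_detected(self):
        track = rainfall(self._sample([1000 + 100 * i for i in range(7)]))
        assert len(track.kataegis_calls) == 1
        call = track.kataegis_calls[0]
        assert call.n_variants == 7
        assert call.mean_imd == pytest.approx(100.0)

    def test_sparse_run_not_called(self):
        track = rainfall(self._sample([10_000 * i for i in range(1, 7)]))
        assert track.kataegis_calls == []

    def test_single_variant_empty_distances(self):
        track = rainfall(self._sample([500]))
        assert track.distances["chr1"] == []

    def test_order_invariance(self):
        pos = [900, 100, 400, 200, 700]
        a = rainfall(self._sample(pos))
        b = rainfall(self._sample(sorted(pos)))
        assert a.distances == b.distances

    def test_duplicate_position_flagged(self):
        from corticophylo.cohort_io import SampleVariantSet

        recs = [
            make_variant("chr1:100:C>T", pos=100, ref="C", alt="T"),
            make_variant("chr1:100:C>G", pos=100, ref="C", alt="G"),
            make_variant("chr1:300:C>T", pos=300, ref="C", alt="T"),
        ]
        track = rainfall(SampleVariantSet("s", recs))
        assert track.has_zero_distance


class TestVariantSpectrum:
    def test_type_tallies(self):
        recs = [
            make_variant("v1", ref="C", alt="T"),
            make_variant("v2", ref="G", alt="A"),
            make_variant("v3", ref="CAT", alt="C", vclass="frameshift_del"),
        ]
        tallies = variant_spectrum(recs)
        assert tallies["variant_type"] == {"SNP": 2, "DEL": 1}
        assert sum(tallies["snv_class"].values()) == 2

    def test_class_tallies_conserve_total(self):
        recs = [make_variant(f"v{i}", ref="C", alt="T") for i in range(5)]
        tallies = variant_spectrum(recs)
        assert sum(tallies["variant_class"].values()) == 5


class TestDemographics:
    def test_published_age_and_diameter_summary(self, cohort):
        d = cohort_demographics(cohort)
        assert d.rounded()["mean_age"] == 38.8
        assert d.rounded()["sd_age"] == 16.5
        assert d.rounded()["mean_diameter"] == 31.9
        # the printed value is the integer 13
        assert round(d.sd_diameter) == 13
        assert d.age_range == (17, 61)

    def test_mean_matches_exact_rational_arithmetic(self, cohort):
        ages = [t.age for t in cohort]
        exact = Fraction(sum(ages), len(ages))
        d = cohort_demographics(cohort)
        assert d.mean_age == pytest.approx(float(exact), abs=0, rel=1e-15)

    def test_all_equal_values_zero_sd(self):
        from corticophylo.cohort_io import CohortTable, Tumor

        tumors = [
            Tumor(f"t{i}", 40, "F", "cushing_disease", "acth_adenoma", 20,
                  True, False, "1 TSS", frozenset())
            for i in range(3)
        ]
        d = cohort_demographics(CohortTable(tumors=tumors))
        assert d.sd_age == 0.0

    def test_counts(self, cohort):
        d = cohort_demographics(cohort)
        assert d.sex_counts == {"F": 9, "M": 1}
        assert d.invasion_count == 9
        assert d.vision_abnormal_count == 8
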