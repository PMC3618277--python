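import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import check_block_merge, random_clustered_calls, random_reference
from varcohort.variants import (
    BLOCK_SUBSTITUTION,
    DELETION,
    HEMIZYGOUS,
    HETEROZYGOUS,
    HOMOZYGOUS,
    INSERTION,
    SNP,
    GenomeCallset,
    GenotypedCall,
    InvalidAlleleError,
    OverlappingVariantsError,
    ReferenceMismatchError,
    VariantCall,
    apply_haplotype,
    build_callset,
    classify_variant_type,
    group_genotyped_calls,
    group_into_blocks,
    het_hom_ratio,
    is_transition,
    maf_spectrum,
    normalize,
    tstv_ratio,
)


class TestClassifyVariantType:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("A", "G", SNP),
            ("", "ACG", INSERTION),
            ("ACG", "", DELETION),
            ("ACGT", "TGCA", BLOCK_SUBSTITUTION),
            ("A", "ACG", INSERTION),  # anchored VCF style
            ("AGG", "A", DELETION),
            ("CAG", "CTG", SNP),  # trims to single-base swap
            ("CG", "T", BLOCK_SUBSTITUTION),
        ],
    )
    def test_examples(self, ref, alt, expected):
        assert classify_variant_type(ref, alt) == expected

    def test_rejects_non_dna(self):
        with pytest.raises(InvalidAlleleError):
            classify_variant_type("AN", "A")

    def test_rejects_identical(self):
        with pytest.raises(InvalidAlleleError):
            classify_variant_type("ACG", "ACG")

    @given(
        ref=st.text(alphabet="ACGT", max_size=6),
        alt=st.text(alphabet="ACGT", max_size=6),
    )
    def test_total_function(self, ref, alt):
        # every non-degenerate pair gets exactly one of the four types
        if ref == alt:
            return
        assert classify_variant_type(ref, alt) in (
            SNP,
            INSERTION,
            DELETION,
            BLOCK_SUBSTITUTION,
        )


class TestIsTransition:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [("A", "G", True), ("C", "T", True), ("A", "C", False), ("G", "T", False)],
    )
    def test_examples(self, ref, alt, expected):
        assert is_transition(VariantCall("c", 0, ref, alt)) is expected

    def test_requires_snp(self):
        with pytest.raises(TypeError):
            is_transition(VariantCall("c", 0, "AC", ""))


class TestNormalize:
    def test_homopolymer_left_shift(self):
        ref = "CCAAAACC"
        v = normalize(VariantCall("c", 5, "A", ""), ref)
        assert (v.start, v.ref_allele, v.alt_allele) == (2, "A", "")
        assert v.vtype == DELETION

    def test_prefix_suffix_trim(self):
        ref = "N" * 10 + "CAG" + "N" * 5
        ref = ref.replace("N", "T")
        v = normalize(VariantCall("c", 10, "CAG", "CTG"), ref)
        assert (v.start, v.ref_allele, v.alt_allele, v.vtype) == (11, "A", "T", SNP)

    def test_reference_mismatch(self):
        with pytest.raises(ReferenceMismatchError):
            normalize(VariantCall("c", 0, "A", "G"), "CCCC")

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_idempotent_and_sequence_preserving(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        ref = random_reference(rng, 40)
        calls = random_clustered_calls(rng, ref, max_calls=1)
        if not calls:
            return
        v = calls[0]
        n1 = normalize(v, ref)
        assert normalize(n1, ref) == n1
        assert apply_haplotype(ref, [v]) == apply_haplotype(ref, [n1])


class TestGroupIntoBlocks:
    REF = "ACGTACGT"

    def test_one_base_between_merges(self):
        calls = [
            VariantCall("c", 2, "G", "T"),
            VariantCall("c", 4, "A", "G"),
        ]
        (block,) = group_into_blocks(calls, self.REF)
        assert block.vtype == BLOCK_SUBSTITUTION
        assert (block.start, block.ref_allele, block.alt_allele) == (2, "GTA", "TTG")
        assert block.n_merged == 2

    def test_two_bases_between_stays_separate(self):
        calls = [
            VariantCall("c", 2, "G", "T"),
            VariantCall("c", 5, "C", "A"),
        ]
        out = group_into_blocks(calls, self.REF)
        assert [v.vtype for v in out] == [SNP, SNP]

    def test_snp_plus_adjacent_deletion(self):
        calls = [
            VariantCall("c", 2, "G", "T"),
            VariantCall("c", 3, "T", ""),
        ]
        (block,) = group_into_blocks(calls, self.REF)
        assert (block.ref_allele, block.alt_allele) == ("GT", "T")
        assert block.vtype == BLOCK_SUBSTITUTION
        assert block.length_change == -1

    def test_overlap_raises(self):
        calls = [
            VariantCall("c", 2, "GT", ""),
            VariantCall("c", 3, "T", "A"),
        ]
        with pytest.raises(OverlappingVariantsError):
            group_into_blocks(calls, self.REF)

    def test_self_cancelling_cluster_rejected(self):
        # inserting "G" directly before a deleted "G" nets out to nothing
        calls = [
            VariantCall("c", 2, "", "G"),
            VariantCall("c", 2, "G", ""),
        ]
        with pytest.raises(InvalidAlleleError):
            group_into_blocks(calls, self.REF)

    def test_unsorted_raises(self):
        calls = [
            VariantCall("c", 4, "A", "G"),
            VariantCall("c", 2, "G", "T"),
        ]
        with pytest.raises(ValueError):
            group_into_blocks(calls, self.REF)

    def test_random_fixtures_lossless_partition(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            ref = random_reference(rng, 90)
            calls = random_clustered_calls(rng, ref)
            if not calls:
                continue
            merged = group_into_blocks(calls, ref)
            check_block_merge(ref, calls, merged)


class TestGroupGenotypedCalls:
    REF = "ACGTACGT"

    def test_homozygous_cluster_merges(self):
        calls = [
            GenotypedCall(VariantCall("c", 2, "G", "T"), HOMOZYGOUS, (1, 1)),
            GenotypedCall(VariantCall("c", 4, "A", "G"), HOMOZYGOUS, (1, 1)),
        ]
        (out,) = group_genotyped_calls(calls, self.REF)
        assert out.variant.vtype == BLOCK_SUBSTITUTION
        assert out.zygosity == HOMOZYGOUS

    def test_unphased_het_cluster_stays_separate(self, caplog):
        calls = [
            GenotypedCall(
                VariantCall("c", 2, "G", "T"), HETEROZYGOUS, (1, 0), phased=False
            ),
            GenotypedCall(
                VariantCall("c", 4, "A", "G"), HETEROZYGOUS, (0, 1), phased=False
            ),
        ]
        with caplog.at_level(logging.WARNING):
            out = group_genotyped_calls(calls, self.REF)
        assert len(out) == 2
        assert "unphased" in caplog.text

    def test_phased_het_cluster_merges_per_haplotype(self):
        calls = [
            GenotypedCall(VariantCall("c", 2, "G", "T"), HETEROZYGOUS, (1, 0)),
            GenotypedCall(VariantCall("c", 4, "A", "G"), HETEROZYGOUS, (1, 0)),
        ]
        (out,) = group_genotyped_calls(calls, self.REF)
        assert out.variant.vtype == BLOCK_SUBSTITUTION
        assert out.zygosity == HETEROZYGOUS


class TestZygosityModel:
    def test_genotyped_call_validation(self):
        v = VariantCall("c", 0, "A", "G")
        with pytest.raises(ValueError):
            GenotypedCall(v, HOMOZYGOUS, (1, 0))
        with pytest.raises(ValueError):
            GenotypedCall(v, HEMIZYGOUS, (1, 1))

    def test_callable_fraction_bounds(self):
        with pytest.raises(ValueError):
            GenomeCallset("x", callable_fraction={"c": 1.2})

    def test_build_callset_combines_haplotypes(self):
        ref = "ACGTACGTACGT"
        hap0 = [VariantCall("c", 2, "G", "T"), VariantCall("c", 8, "A", "C")]
        hap1 = [VariantCall("c", 8, "A", "C")]
        cs = build_callset("ind", "female", {"c": [hap0, hap1]}, ref)
        by_key = cs.calls_by_key()
        assert by_key[("c", 2, "G", "T")].zygosity == HETEROZYGOUS
        assert by_key[("c", 8, "A", "C")].zygosity == HOMOZYGOUS

    def test_build_callset_haploid(self):
        ref = "ACGTACGT"
        cs = build_callset(
            "ind",
            "male",
            {"x": [[VariantCall("x", 2, "G", "T")]]},
            ref,
            haploid_contigs=["x"],
        )
        assert cs.calls[0].zygosity == HEMIZYGOUS


class TestSummaryRatios:
    def test_tstv_examples(self):
        snps = [
            VariantCall("c", 0, "A", "G"),
            VariantCall("c", 1, "C", "T"),
            VariantCall("c", 2, "A", "C"),
        ]
        assert tstv_ratio(snps) == 2.0
        assert tstv_ratio([]) is None

    def test_tstv_binomial_recovery(self):
        # SNPs drawn with transition probability 2.13 / 3.13
        rng = np.random.default_rng(7)
        p_ts = 2.13 / 3.13
        snps = []
        for i in range(10_000):
            if rng.random() < p_ts:
                snps.append(VariantCall("c", i, "A", "G"))
            else:
                snps.append(VariantCall("c", i, "A", "C"))
        assert tstv_ratio(snps) == pytest.approx(2.13, abs=0.15)

    def test_het_hom_examples(self):
        v = VariantCall("c", 0, "A", "G")
        het = GenotypedCall(v, HETEROZYGOUS, (0, 1))
        hom = GenotypedCall(v, HOMOZYGOUS, (1, 1))
        hemi = GenotypedCall(v, HEMIZYGOUS, (1,))
        assert het_hom_ratio([het, het, hom]) == 2.0
        assert het_hom_ratio([hom, hom]) == 0.0
        assert het_hom_ratio([het]) is None  # no homozygotes: undefined
        assert het_hom_ratio([het, het, hom, hemi]) == 2.0  # hemi excluded


class TestMafSpectrum:
    @staticmethod
    def _cohort_with_genotypes(zygosities):
        v = VariantCall("c", 10, "A", "G")
        cohort = []
        for i, zyg in enumerate(zygosities):
            calls = []
            if zyg is not None:
                alleles = {
                    HETEROZYGOUS: (0, 1),
                    HOMOZYGOUS: (1, 1),
                }[zyg]
                calls = [GenotypedCall(v, zyg, alleles)]
            cohort.append(GenomeCallset(f"i{i}", calls=calls))
        return cohort

    def test_single_het_in_four_diploids(self):
        cohort = self._cohort_with_genotypes([HETEROZYGOUS, None, None, None])
        counts, edges = maf_spectrum(cohort, [0.05])
        # MAF = 1/8 = 0.125 -> lands in (0.05, 0.5]
        assert list(edges) == [0.0, 0.05, 0.5]
        assert list(counts) == [0, 1]

    def test_monomorphic_excluded(self):
        cohort = self._cohort_with_genotypes([HOMOZYGOUS] * 4)
        counts, _ = maf_spectrum(cohort, [0.05])
        assert counts.sum() == 0

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            maf_spectrum([], [0.05])

    def test_counts_sum_to_distinct_variants(self, callsets):
        from varcohort.variants import allele_frequencies

        counts, _ = maf_spectrum(callsets, [0.01, 0.05, 0.1, 0.2])
        freqs = allele_frequencies(callsets)
        n_polymorphic = sum(
            1 for _, ac, an in freqs.values() if min(ac / an, 1 - ac / an) > 0
        )
        assert counts.sum() == n_polymorphic


class TestTypeAdditivity:
    def test_callset_type_partition(self, callsets):
        # snp + ins + del + block == total calls for every callset
        for cs in callsets:
            by_type = {t: 0 for t in (SNP, INSERTION, DELETION, BLOCK_SUBSTITUTION)}
            for call in cs.calls:
                by_type[call.variant.vtype] += 1
            assert sum(by_type.values()) == len(cs.calls)
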