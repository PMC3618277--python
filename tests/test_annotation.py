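import pytest

from varcohort.annotation import (
    CDS,
    INTERGENIC,
    INTRON,
    MISSENSE,
    NONSENSE,
    NONSTOP,
    NO_EFFECT,
    SPLICE_ACCEPTOR,
    SPLICE_DONOR,
    SYNONYMOUS,
    FRAMESHIFT,
    FRAMESHIFT_PRESERVING,
    UTR,
    AnnotatedVariant,
    GeneEffect,
    TranscriptIndex,
    TranscriptModel,
    annotate_cohort,
    annotate_variant,
    coding_effect,
    is_lof,
    locate,
)
from varcohort.variants import GenotypedCall, GenomeCallset, HETEROZYGOUS, VariantCall
from varcohort.variants import reverse_complement


@pytest.fixture()
def multi_exon_plus():
    # exons [10,30) [40,60) [70,90); CDS 15..80 on the + strand
    return TranscriptModel(
        gene_id="gA",
        transcript_id="tA",
        contig="c",
        strand="+",
        exons=((10, 30), (40, 60), (70, 90)),
        cds_start=15,
        cds_end=80,
    )


class TestTranscriptModel:
    def test_derived_intervals_plus(self, multi_exon_plus):
        t = multi_exon_plus
        assert t.cds_intervals == ((15, 30), (40, 60), (70, 80))
        assert t.utr_intervals == ((10, 15), (80, 90))
        assert t.utr5_intervals == ((10, 15),)
        assert t.utr3_intervals == ((80, 90),)
        assert t.splice_donors == ((30, 32), (60, 62))
        assert t.splice_acceptors == ((38, 40), (68, 70))
        assert t.cds_length == 45

    def test_derived_intervals_minus(self):
        t = TranscriptModel("gB", "tB", "c", "-", ((10, 30), (40, 60)), 15, 55)
        # on the minus strand, donors sit at the right intron edge
        assert t.splice_donors == ((38, 40),)
        assert t.splice_acceptors == ((30, 32),)
        assert t.utr5_intervals == ((55, 60),)
        assert t.utr3_intervals == ((10, 15),)

    def test_coordinate_mapping_roundtrip(self, multi_exon_plus):
        t = multi_exon_plus
        for idx in range(t.cds_length):
            assert t.genomic_to_cds(t.cds_to_genomic(idx)) == idx
        assert t.genomic_to_cds(5) is None

    def test_minus_strand_mapping(self):
        t = TranscriptModel("gB", "tB", "c", "-", ((10, 30),), 12, 27)
        # CDS index 0 maps to the genomic right end of the CDS
        assert t.cds_to_genomic(0) == 26
        assert t.cds_to_genomic(t.cds_length - 1) == 12

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            TranscriptModel("g", "t", "c", "*", ((0, 10),), 0, 9)
        with pytest.raises(ValueError):
            TranscriptModel("g", "t", "c", "+", ((0, 10), (5, 15)), 0, 9)
        with pytest.raises(ValueError):
            TranscriptModel("g", "t", "c", "+", ((0, 10),), 0, 12)


class TestLocate:
    def test_hierarchy_across_isoforms(self, multi_exon_plus):
        # intron of A, CDS of B -> cds wins
        other = TranscriptModel("gB", "tB", "c", "+", ((30, 39),), 30, 39)
        v = VariantCall("c", 33, "A", "G")
        index = TranscriptIndex([multi_exon_plus, other])
        assert locate(v, index) == CDS

    def test_splice_donor_first_intronic_base(self, multi_exon_plus):
        v = VariantCall("c", 30, "A", "G")
        assert locate(v, [multi_exon_plus]) == SPLICE_DONOR

    def test_splice_acceptor(self, multi_exon_plus):
        v = VariantCall("c", 39, "A", "G")
        assert locate(v, [multi_exon_plus]) == SPLICE_ACCEPTOR

    def test_intron_interior(self, multi_exon_plus):
        v = VariantCall("c", 35, "A", "G")
        assert locate(v, [multi_exon_plus]) == INTRON

    def test_intergenic(self, multi_exon_plus):
        assert locate(VariantCall("c", 5, "A", "G"), [multi_exon_plus]) == INTERGENIC
        assert locate(VariantCall("x", 33, "A", "G"), [multi_exon_plus]) == INTERGENIC

    def test_utr(self, multi_exon_plus):
        assert locate(VariantCall("c", 12, "A", "G"), [multi_exon_plus]) == UTR

    def test_boundary_spanning_deletion_is_cds(self, multi_exon_plus):
        # deletion straddling the CDS/intron boundary takes the highest class
        v = VariantCall("c", 28, "NNNN".replace("N", "A"), "")
        assert locate(v, [multi_exon_plus]) == CDS

    def test_hierarchy_idempotence(self, multi_exon_plus):
        # adding a lower-priority overlapping transcript never changes the class
        v = VariantCall("c", 20, "A", "G")
        alone = locate(v, [multi_exon_plus])
        wide_intron = TranscriptModel(
            "gC", "tC", "c", "+", ((0, 5), (95, 100)), 0, 100
        )
        assert locate(v, [multi_exon_plus, wide_intron]) == alone


class TestCodingEffect:
    REF = "ATGGAATAA" + "T" * 6

    @pytest.fixture()
    def tiny(self):
        return TranscriptModel("g", "t", "c", "+", ((0, 9),), 0, 9)

    def test_missense(self, tiny):
        v = VariantCall("c", 3, "G", "A")  # GAA -> AAA (Glu -> Lys)
        assert coding_effect(v, tiny, self.REF) == MISSENSE

    def test_nonsense(self, tiny):
        v = VariantCall("c", 3, "G", "T")  # GAA -> TAA
        assert coding_effect(v, tiny, self.REF) == NONSENSE

    def test_nonstop(self, tiny):
        v = VariantCall("c", 6, "T", "C")  # TAA -> CAA
        assert coding_effect(v, tiny, self.REF) == NONSTOP

    def test_synonymous(self, tiny):
        v = VariantCall("c", 5, "A", "G")  # GAA -> GAG, both Glu
        assert coding_effect(v, tiny, self.REF) == SYNONYMOUS

    def test_frameshift_rule(self, tiny):
        assert coding_effect(VariantCall("c", 3, "GA", ""), tiny, self.REF) == FRAMESHIFT
        assert (
            coding_effect(VariantCall("c", 3, "GAA", ""), tiny, self.REF)
            == FRAMESHIFT_PRESERVING
        )
        assert (
            coding_effect(VariantCall("c", 4, "", "CCC"), tiny, self.REF)
            == FRAMESHIFT_PRESERVING
        )

    def test_length_conserving_block(self, tiny):
        # GAA -> AAG: two changed columns in one codon, Glu -> Lys
        v = VariantCall("c", 3, "GAA", "AAG")
        assert coding_effect(v, tiny, self.REF) == MISSENSE

    def test_mito_code(self):
        # AGA codes Arg nuclear but stop in the vertebrate mito code
        ref = "ATGAAATAA"
        t = TranscriptModel("g", "t", "m", "+", ((0, 9),), 0, 9)
        v = VariantCall("m", 4, "A", "G")  # AAA -> AGA
        assert coding_effect(v, t, {"m": ref}, table_id=2) == NONSENSE
        assert coding_effect(v, t, {"m": ref}, table_id=1) == MISSENSE


class TestStrandMetamorphic:
    def test_minus_strand_equals_mirrored_plus(self, rng):
        # a minus-strand gene annotated in place must match its
        # reverse-complemented plus-strand mirror
        L = 120
        seq = "".join(rng.choice(list("ACGT"), size=L))
        cds = "ATG" + "GAACCTTGG" * 3 + "TAA"
        start = 40
        seq = seq[:start] + reverse_complement(cds) + seq[start + len(cds):]
        t_minus = TranscriptModel(
            "g", "t", "c", "-", ((start, start + len(cds)),), start, start + len(cds)
        )
        mirror_seq = reverse_complement(seq)
        m_start = L - (start + len(cds))
        t_plus = TranscriptModel(
            "g", "t", "c", "+", ((m_start, m_start + len(cds)),), m_start, m_start + len(cds)
        )
        assert t_minus.cds_sequence(seq) == cds
        assert t_plus.cds_sequence(mirror_seq) == cds
        for pos in range(start, start + len(cds)):
            ref_b = seq[pos]
            for alt_b in "ACGT":
                if alt_b == ref_b:
                    continue
                v_minus = VariantCall("c", pos, ref_b, alt_b)
                v_plus = VariantCall(
                    "c",
                    L - 1 - pos,
                    reverse_complement(ref_b),
                    reverse_complement(alt_b),
                )
                assert coding_effect(v_minus, t_minus, seq) == coding_effect(
                    v_plus, t_plus, mirror_seq
                )


class TestIsLof:
    @pytest.mark.parametrize(
        "region,effect,expected",
        [
            (CDS, NONSENSE, True),
            (CDS, NONSTOP, True),
            (CDS, FRAMESHIFT, True),
            (CDS, SYNONYMOUS, False),
            (CDS, MISSENSE, False),
            (CDS, FRAMESHIFT_PRESERVING, False),
            (SPLICE_ACCEPTOR, NO_EFFECT, True),
            (SPLICE_DONOR, NO_EFFECT, True),
            (INTRON, NO_EFFECT, False),
            (INTERGENIC, NO_EFFECT, False),
        ],
    )
    def test_definition(self, region, effect, expected):
        ann = AnnotatedVariant(VariantCall("c", 0, "A", "G"), region, effect)
        assert is_lof(ann) is expected

    def test_region_effect_consistency_enforced(self):
        with pytest.raises(ValueError):
            AnnotatedVariant(VariantCall("c", 0, "A", "G"), INTRON, MISSENSE)


class TestAnnotateCohort:
    def test_three_snp_example(self):
        # one genome: cds-synonymous, intron, intergenic
        ref = {"c": "ATGGAATAA" + "T" * 91}
        t1 = TranscriptModel("g1", "t1", "c", "+", ((0, 9), (30, 40)), 0, 9)
        calls = [
            GenotypedCall(VariantCall("c", 5, "A", "G"), HETEROZYGOUS, (0, 1)),
            GenotypedCall(VariantCall("c", 20, "T", "C"), HETEROZYGOUS, (0, 1)),
            GenotypedCall(VariantCall("c", 60, "T", "A"), HETEROZYGOUS, (0, 1)),
        ]
        cohort = [GenomeCallset("i0", calls=calls)]
        ann = annotate_cohort(cohort, [t1], ref)
        counts = ann.distinct_class_counts()["snp"]
        assert counts.total == 3
        assert counts.by_region == {CDS: 1, INTRON: 1, INTERGENIC: 1}
        assert counts.intragenic == 2
        assert counts.by_effect == {SYNONYMOUS: 1}

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            annotate_cohort([], [], {"c": "ACGT"})

    def test_contig_mismatch_rejected(self):
        calls = [
            GenotypedCall(VariantCall("zz", 1, "A", "G"), HETEROZYGOUS, (0, 1))
        ]
        with pytest.raises(ValueError):
            annotate_cohort([GenomeCallset("i", calls=calls)], [], {"c": "ACGT"})

    def test_region_partition(self, cohort_annotation):
        # intergenic + intron + utr + splice + cds == total, per class
        for counts in cohort_annotation.distinct_class_counts().values():
            assert sum(counts.by_region.values()) == counts.total

    def test_coding_snp_effect_partition(self, cohort_annotation):
        snp = cohort_annotation.distinct_class_counts()["snp"]
        assert snp.by_effect.get(SYNONYMOUS, 0) + snp.non_synonymous == snp.coding

    def test_coding_indel_effect_partition(self, cohort_annotation):
        indel = cohort_annotation.distinct_class_counts()["indel"]
        assert (
            indel.by_effect.get(FRAMESHIFT, 0)
            + indel.by_effect.get(FRAMESHIFT_PRESERVING, 0)
            == indel.coding
        )

    def test_count_table_structure(self, cohort_annotation):
        table = cohort_annotation.count_table()
        snp_rows = table[table.variant_class == "snp"].set_index("category")
        assert (
            snp_rows.loc["intergenic", "total"] + snp_rows.loc["intragenic", "total"]
            == snp_rows.loc["total", "total"]
        )
        assert (
            snp_rows.loc["synonymous", "total"]
            + snp_rows.loc["non_synonymous", "total"]
            == snp_rows.loc["coding", "total"]
        )


class TestGeneEffects:
    def test_gene_level_splice_lof(self, multi_exon_plus):
        index = TranscriptIndex([multi_exon_plus])
        ann = annotate_variant(VariantCall("c", 30, "A", "G"), index, "A" * 100)
        assert ann.gene_effects["gA"] == GeneEffect(SPLICE_DONOR, NO_EFFECT)
        assert ann.lof_genes() == ("gA",)
        assert ann.is_lof
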