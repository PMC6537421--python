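import pytest

from vafphase.comphet import (
    AnnotatedVariant,
    GeneSummary,
    GeneVariantSet,
    assign_group,
    classify_set_score,
    detect_gene_events,
    is_clinvar_pathogenic,
    is_damaging_cadd,
    summarize_gene,
)


def var(pos=100, cadd=None, hap=None, homozygous=False, clinvar=(), lof=False,
        afs=(), gene="G1"):
    return AnnotatedVariant(key=("1", pos, "A", "G"), gene=gene, cadd=cadd,
                            clinvar_labels=tuple(clinvar), lof=lof,
                            allele_freqs=tuple(afs), hap=hap, homozygous=homozygous)


class TestDamagingRules:
    @pytest.mark.parametrize("cadd,expect", [(15.0, True), (14.9, False), (None, False)])
    def test_cadd_threshold_inclusive(self, cadd, expect):
        assert is_damaging_cadd(var(cadd=cadd)) is expect

    @pytest.mark.parametrize("labels,expect", [
        (["Pathogenic", "Likely pathogenic", "Benign", "Benign"], True),  # exactly half
        (["Pathogenic", "Benign", "Benign"], False),
        ([], False),
        (["Likely_Pathogenic", "Pathogenic"], True),
    ])
    def test_clinvar_majority(self, labels, expect):
        assert is_clinvar_pathogenic(labels) is expect


class TestGeneEvents:
    def test_both_haplotypes_trans(self):
        gs = GeneVariantSet("G1", [var(100, cadd=20, hap=0), var(200, cadd=18, hap=1)])
        assert detect_gene_events(gs) == "trans"

    def test_same_haplotype_cis(self):
        gs = GeneVariantSet("G1", [var(100, cadd=20, hap=0), var(200, cadd=18, hap=0)])
        assert detect_gene_events(gs) == "cis"

    def test_unphased_pair_unresolved(self):
        gs = GeneVariantSet("G1", [var(100, cadd=20), var(200, cadd=18)])
        assert detect_gene_events(gs) == "unresolved"

    def test_homozygous_damaging_is_trans(self):
        gs = GeneVariantSet("G1", [var(100, cadd=20, homozygous=True)])
        assert detect_gene_events(gs) == "trans"

    def test_single_damaging_mono(self):
        gs = GeneVariantSet("G1", [var(100, cadd=20, hap=0), var(200, cadd=5, hap=1)])
        assert detect_gene_events(gs) == "mono"

    def test_no_damaging_none(self):
        gs = GeneVariantSet("G1", [var(100, cadd=3)])
        assert detect_gene_events(gs) == "none"

    def test_trans_cis_mutually_exclusive_when_phased(self):
        for haps in [(0, 0), (0, 1), (1, 0), (1, 1)]:
            gs = GeneVariantSet("G1", [var(100, cadd=20, hap=haps[0]),
                                       var(200, cadd=20, hap=haps[1])])
            assert detect_gene_events(gs) in ("trans", "cis")


class TestSetScore:
    def test_non_compensatory_at_printed_threshold(self):
        # individual {2, 4}: range 2, upper threshold 4 + 1.5*2 = 7
        assert classify_set_score(7.5, [2, 4]).label == "non_compensatory"
        assert classify_set_score(7.0, [2, 4]).label == "non_compensatory"  # >= is inclusive

    def test_compensatory_at_printed_threshold(self):
        # lower threshold 2 - 1.5*2 = -1
        assert classify_set_score(-1.0, [2, 4]).label == "compensatory"
        assert classify_set_score(-1.5, [2, 4]).label == "compensatory"

    def test_neutral_inside_thresholds(self):
        assert classify_set_score(4.0, [2, 4]).label == "neutral"
        assert classify_set_score(0.5, [2, 4]).label == "neutral"
        assert classify_set_score(6.9, [2, 4]).label == "neutral"

    def test_requires_two_scores(self):
        with pytest.raises(ValueError, match=">= 2"):
            classify_set_score(1.0, [2])

    def test_permutation_invariant(self):
        assert classify_set_score(7.5, [4, 2]) == classify_set_score(7.5, [2, 4])

    def test_degenerate_zero_range(self):
        call = classify_set_score(3.0001, [3, 3])
        assert call.label == "non_compensatory" and call.degenerate
        assert classify_set_score(2.9999, [3, 3]).label == "compensatory"


def summary(gene="G1", event="none", clinvar_lof=False, cadd=False, set_class=None):
    return GeneSummary(gene=gene, event=event, clinvar_lof=clinvar_lof,
                       cadd_damaging=cadd, set_class=set_class)


class TestAssignGroup:
    def test_trans_beats_mono_cadd(self):
        s = [summary("G1", event="trans", cadd=True), summary("G2", cadd=True)]
        assert assign_group(s, "comphet") == "Trans"

    def test_comphet_precedence_chain(self):
        assert assign_group([summary(event="cis"), summary("G2", clinvar_lof=True)],
                            "comphet") == "Cis"
        assert assign_group([summary(clinvar_lof=True), summary("G2", cadd=True)],
                            "comphet") == "ClinVar/LOF"
        assert assign_group([summary(cadd=True)], "comphet") == "CADD"

    def test_hmmvar_scheme(self):
        s = [summary(set_class="non_compensatory"), summary("G2", clinvar_lof=True)]
        assert assign_group(s, "hmmvar") == "Non-Compensatory"
        assert assign_group([summary(set_class="compensatory")], "hmmvar") == "Compensatory"

    def test_no_qualifying_variants(self):
        assert assign_group([summary()], "comphet") == "none"

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            assign_group([], "bogus")

    def test_invariant_to_gene_order(self):
        s = [summary("G1", event="trans"), summary("G2", event="cis")]
        assert assign_group(s) == assign_group(list(reversed(s)))

    def test_invariant_to_hap_flip(self):
        """Flipping all hap labels within a gene cannot change the grouping."""
        variants = [var(100, cadd=20, hap=0), var(200, cadd=18, hap=1)]
        flipped = [var(100, cadd=20, hap=1), var(200, cadd=18, hap=0)]
        a = summarize_gene(GeneVariantSet("G1", variants))
        b = summarize_gene(GeneVariantSet("G1", flipped))
        assert a.event == b.event
        assert assign_group([a]) == assign_group([b])


class TestSummarizeGene:
    def test_lof_requires_rarity_in_all_groups(self):
        rare = GeneVariantSet("G1", [var(100, lof=True, afs=(0.01, 0.02))])
        common = GeneVariantSet("G1", [var(100, lof=True, afs=(0.01, 0.2))])
        assert summarize_gene(rare).clinvar_lof
        assert not summarize_gene(common).clinvar_lof

    def test_set_scores_propagate(self):
        gs = GeneVariantSet("G1", [var(100, cadd=16, hap=0), var(200, cadd=17, hap=0)],
                            set_score=7.5, individual_scores=[2, 4])
        s = summarize_gene(gs)
        assert s.set_class == "non_compensatory" and s.event == "cis"
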