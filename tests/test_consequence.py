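"""SNV consequence classification against brute-force translation oracles."""

import pytest

from _oracles import genomic_base, oracle_classify_snv
from famvar import TranscriptModel, VariantSite, classify_snv, \
    filter_protein_disrupting
from famvar.consequence import AnnotationError
from famvar.core import ConsequenceAnnotation, GenotypeCall, VariantRecord

BASES = "ACGT"


@pytest.fixture
def single_exon_model():
    # Lys-Lys toy: ATG AAA TAA
    return TranscriptModel(gene="MINI", chrom="chr1", strand="+",
                           cds_intervals=[(101, 109)],
                           cds_sequence="ATGAAATAA")


class TestWorkedExamples:
    def test_synonymous(self, single_exon_model):
        ann = classify_snv(VariantSite("chr1", 106, "A", "G"),
                           single_exon_model)
        assert ann.consequence == "synonymous"
        assert ann.codon_change == "AAA6AAG"

    def test_missense(self, single_exon_model):
        ann = classify_snv(VariantSite("chr1", 104, "A", "G"),
                           single_exon_model)
        assert ann.consequence == "missense"
        assert ann.aa_change == "p.K2E"

    def test_nonsense(self, single_exon_model):
        ann = classify_snv(VariantSite("chr1", 104, "A", "T"),
                           single_exon_model)
        assert ann.consequence == "nonsense"

    def test_intergenic(self, single_exon_model):
        ann = classify_snv(VariantSite("chr1", 50, "A", "G"),
                           single_exon_model)
        assert ann.consequence == "intergenic"

    def test_ref_mismatch_is_annotation_error(self, single_exon_model):
        with pytest.raises(AnnotationError):
            classify_snv(VariantSite("chr1", 104, "C", "G"),
                         single_exon_model)


@pytest.mark.parametrize("model_name", ["toy_transcript_plus",
                                        "toy_transcript_minus"])
def test_exhaustive_against_translation_oracle(model_name, request):
    """Every possible substitution at every position across the gene span
    (both strands) matches full-sequence mutation + translation."""
    model = request.getfixturevalue(model_name)
    lo, hi = model.span
    for pos in range(lo - 5, hi + 6):
        idx = model.cds_index(pos)
        for alt in BASES:
            if idx is not None:
                ref = genomic_base(model, pos)
                if alt == ref:
                    continue
            else:
                ref = "A" if alt != "A" else "C"
            got = classify_snv(VariantSite(model.chrom, pos, ref, alt),
                               model)
            want = oracle_classify_snv(pos, ref, alt, model)
            assert got.consequence == want, (pos, ref, alt)


def test_strand_symmetry(toy_transcript_plus, toy_transcript_minus):
    """The - strand mirror yields the same amino-acid outcome as its
    + strand counterpart at every coding position."""
    plus, minus = toy_transcript_plus, toy_transcript_minus
    lo, hi = plus.span
    for pos in range(lo, hi + 1):
        idx = plus.cds_index(pos)
        if idx is None:
            continue
        mirror = 1000 - pos
        assert minus.cds_index(mirror) == idx
        ref_p = genomic_base(plus, pos)
        for alt_p in BASES:
            if alt_p == ref_p:
                continue
            comp = dict(zip("ACGT", "TGCA"))
            ann_p = classify_snv(VariantSite("chr1", pos, ref_p, alt_p),
                                 plus)
            ann_m = classify_snv(
                VariantSite("chr1", mirror, comp[ref_p], comp[alt_p]),
                minus)
            assert ann_p.consequence == ann_m.consequence
            assert ann_p.aa_change == ann_m.aa_change


def test_splice_sites_flank_internal_edges_only(toy_transcript_plus):
    m = toy_transcript_plus   # exons (101,109) and (201,206)
    for pos, want in [(110, "splice_site"), (111, "splice_site"),
                      (112, "noncoding_in_gene"),
                      (199, "splice_site"), (200, "splice_site"),
                      (198, "noncoding_in_gene"),
                      (100, "intergenic"), (207, "intergenic")]:
        ann = classify_snv(VariantSite("chr1", pos, "A", "G"), m)
        assert ann.consequence == want, pos


# protein-disrupting filter --------------------------------------------------

def _annotated(labels):
    out = []
    for i, label in enumerate(labels):
        rec = VariantRecord(
            site=VariantSite("chr1", 1000 + i, "A", "G"),
            genotypes={"s": GenotypeCall("s", "het")})
        out.append((rec, ConsequenceAnnotation(gene=f"G{i}",
                                               consequence=label)))
    return out


class TestProteinDisruptingFilter:
    def test_excluded_classes_dropped(self):
        kept = filter_protein_disrupting(_annotated(
            ["missense", "synonymous", "intronic", "nonsense"]))
        assert [ann.consequence for _, ann in kept] == \
            ["missense", "nonsense"]

    def test_empty_input(self):
        assert filter_protein_disrupting([]) == []

    def test_all_missense_is_noop(self):
        annotated = _annotated(["missense"] * 7)
        assert filter_protein_disrupting(annotated) == annotated

    def test_indel_classes_retained(self):
        kept = filter_protein_disrupting(_annotated(
            ["frameshift", "inframe_indel", "utr"]))
        assert [ann.consequence for _, ann in kept] == \
            ["frameshift", "inframe_indel"]

    def test_unknown_label_raises(self):
        annotated = _annotated(["missense"])
        annotated[0][1].__dict__["consequence"] = "weird"
        with pytest.raises(AnnotationError):
            filter_protein_disrupting(annotated)


def test_model_invariants_enforced():
    with pytest.raises(ValueError):   # length not divisible by 3
        TranscriptModel("X", "chr1", "+", [(1, 4)], "ATGC")
    with pytest.raises(ValueError):   # sequence/interval length mismatch
        TranscriptModel("X", "chr1", "+", [(1, 6)], "ATG")
    with pytest.raises(ValueError):   # overlapping intervals
        TranscriptModel("X", "chr1", "+", [(1, 6), (4, 9)], "ATGATGATG")
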