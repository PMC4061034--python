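"""Domain-type invariants and round trips through the standard formats."""

import logging
import random
import textwrap

import pytest

from famvar import (CascadeReport, ContingencyTable2x2, GenotypeCall,
                    IndelReadSupport, PopulationRecord, VariantSite)
from famvar.core import PedigreeError, infer_vclass
from famvar.io import (FieldMap, VcfConfigError, read_pedigree, read_targets,
                       read_variants, write_variants)


class TestVariantSite:
    def test_vclass_inference(self):
        assert infer_vclass("A", "G") == "SNV"
        assert infer_vclass("A", "AT") == "insertion"
        assert infer_vclass("AT", "A") == "deletion"
        with pytest.raises(ValueError):
            infer_vclass("AT", "GC")

    @pytest.mark.parametrize("kwargs", [
        dict(chrom="chr1", pos=0, ref="A", alt="G"),
        dict(chrom="chr1", pos=5, ref="A", alt="A"),
        dict(chrom="chr1", pos=5, ref="A", alt="AT", vclass="SNV"),
    ])
    def test_invariants_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VariantSite(**kwargs)

    def test_key(self):
        assert VariantSite("chr3", 196921405, "A", "G").key == \
            "chr3:196921405:A:G"


def test_indel_support_bounds():
    with pytest.raises(ValueError):
        IndelReadSupport(supporting_reads=5, total_reads=4)
    assert IndelReadSupport(7, 14).fraction == 0.5


def test_population_record_invariants():
    with pytest.raises(ValueError):
        PopulationRecord("dbSNP", present=True, af=1.5)
    with pytest.raises(ValueError):
        PopulationRecord("KG1000", present=False, af=0.2)
    with pytest.raises(ValueError):
        PopulationRecord("NOPE", present=True)


def test_contingency_table_invariants():
    t = ContingencyTable2x2(3, 557, 0, 802)
    assert t.n == 1362
    assert t.margins == (560, 802, 3, 1359)
    with pytest.raises(ValueError):
        ContingencyTable2x2(-1, 1, 1, 1)
    with pytest.raises(ValueError):
        ContingencyTable2x2(0, 0, 0, 0)


def test_cascade_report_monotonicity_guard():
    rep = CascadeReport()
    rep.add_stage("total", {"s1": 10})
    rep.add_stage("qc", {"s1": 7})
    rep.check_monotone()
    rep.add_stage("bad", {"s1": 9})
    with pytest.raises(ValueError):
        rep.check_monotone()
    with pytest.raises(ValueError):
        rep.add_stage("neg", {"s1": -1})


# VCF ------------------------------------------------------------------------

VCF_HEADER = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1>
    ##INFO=<ID=DB,Number=0,Type=Flag,Description="dbSNP">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
    """)


def _write_vcf(tmp_path, body, name="t.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + textwrap.dedent(body))
    return path


def test_read_single_sample_vcf(tmp_path):
    path = _write_vcf(tmp_path, """\
        chr1\t100\t.\tA\tG\t.\t.\t.\tGT:GQ:DP\t0/1:45:30
        chr1\t200\t.\tC\tT\t.\t.\tDB\tGT:GQ:DP\t1/1:50:22
        chr1\t300\t.\tG\tA\t.\t.\t.\tGT:GQ:DP\t0/0:60:18
        """)
    samples, records = read_variants(path)
    assert samples == ["S1"]
    assert len(records) == 3
    assert records[0].genotypes["S1"].zygosity == "het"
    assert records[1].genotypes["S1"].zygosity == "hom_alt"
    assert records[1].qualities["S1"].in_dbsnp
    assert records[0].qualities["S1"].genotype_quality == 45
    assert records[2].qualities["S1"].depth == 18


def test_multiallelic_record_is_decomposed(tmp_path):
    # hand-decomposed: alt G carried het, alt T absent for this sample
    path = _write_vcf(tmp_path, """\
        chr1\t500\t.\tA\tG,T\t.\t.\t.\tGT:GQ:DP\t0/1:45:30
        """)
    _, records = read_variants(path)
    assert len(records) == 2
    assert [(r.site.alt, r.genotypes["S1"].zygosity) for r in records] == \
        [("G", "het"), ("T", "hom_ref")]
    assert all(r.site.pos == 500 and r.site.chrom == "chr1"
               for r in records)


def test_missing_gq_is_reported_not_defaulted(tmp_path, caplog):
    path = _write_vcf(tmp_path, """\
        chr1\t100\t.\tA\tG\t.\t.\t.\tGT:DP\t0/1:30
        """)
    with caplog.at_level(logging.WARNING, logger="famvar"):
        _, records = read_variants(path)
    assert records[0].qualities["S1"].genotype_quality is None
    assert any("GQ" in r.message for r in caplog.records)


def test_unknown_format_key_is_config_error(tmp_path):
    path = _write_vcf(tmp_path, """\
        chr1\t100\t.\tA\tG\t.\t.\t.\tGT:GQ:DP\t0/1:45:30
        """)
    with pytest.raises(VcfConfigError):
        read_variants(path, FieldMap(genotype_quality="GQX"))


def test_vcf_round_trip_preserves_sites_and_zygosity(tmp_path, small_bundle):
    subset = small_bundle.records[:200]
    out = tmp_path / "rt.vcf"
    write_variants(small_bundle.samples, subset, out)
    samples, back = read_variants(out)
    assert samples == small_bundle.samples
    assert len(back) == len(subset)
    for orig, rt in zip(subset, back):
        assert (orig.site.chrom, orig.site.pos, orig.site.ref,
                orig.site.alt) == (rt.site.chrom, rt.site.pos,
                                   rt.site.ref, rt.site.alt)
        for s in samples:
            assert orig.genotypes[s].zygosity == rt.genotypes[s].zygosity


# PED ------------------------------------------------------------------------

QUARTET_PED = [
    "FAMA father 0 grandmother 1 2",
    "FAMA daughter father mother 2 2",
    "FAMA mother 0 0 2 1",
    "FAMA grandmother 0 0 2 1",
]


def test_read_quartet_pedigree(tmp_path):
    path = tmp_path / "fam.ped"
    path.write_text("\n".join(QUARTET_PED) + "\n")
    ped = read_pedigree(path, roles={"father": "exome_case",
                                    "daughter": "exome_case"})
    assert ped.ids_with(affected="affected") == ["daughter", "father"]
    assert ped.samples["father"].role == "exome_case"
    # founder convention: father id "0" means no paternal link
    assert ped.parents["father"] == (None, "grandmother")
    assert "mother" not in ped.parents
    assert ped.trios() == [("daughter", "father", "mother")]


def test_pedigree_build_is_row_order_independent(tmp_path):
    rng = random.Random(0)
    reference = None
    for _ in range(5):
        rows = QUARTET_PED[:]
        rng.shuffle(rows)
        path = tmp_path / "shuffled.ped"
        path.write_text("\n".join(rows) + "\n")
        ped = read_pedigree(path)
        snapshot = (sorted(ped.samples), sorted(ped.parents.items()))
        if reference is None:
            reference = snapshot
        assert snapshot == reference


def test_pedigree_structural_errors(tmp_path):
    dup = tmp_path / "dup.ped"
    dup.write_text("F a 0 0 1 1\nF a 0 0 1 1\n")
    with pytest.raises(PedigreeError):
        read_pedigree(dup)
    cyc = tmp_path / "cyc.ped"
    cyc.write_text("F a b 0 1 1\nF b a 0 1 1\n")
    with pytest.raises(PedigreeError):
        read_pedigree(cyc)


def test_read_targets_converts_bed_coordinates(tmp_path):
    bed = tmp_path / "t.bed"
    bed.write_text("chr1\t999\t2000\nchr2\t0\t100\n")
    targets = read_targets(bed)
    assert targets == {"chr1": [(1000, 2000)], "chr2": [(1, 100)]}
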