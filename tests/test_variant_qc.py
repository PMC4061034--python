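"""Quality-control criteria, indel zygosity banding and target restriction."""

import pytest
from hypothesis import given, strategies as st

from famvar import (GenotypeCall, IndelReadSupport, QCThresholds, SiteQuality,
                    VariantRecord, VariantSite, call_indel_zygosity, qc_snv,
                    restrict_to_targets)

THR = QCThresholds()


def quality(gq=50, dp=30, cn=1.5, dist=100, db=False):
    return SiteQuality(genotype_quality=gq, depth=dp, copy_number=cn,
                       nearest_snp_distance=dist, in_dbsnp=db)


class TestSnvQC:
    @pytest.mark.parametrize("q, passed, criterion", [
        # the four criteria, one at a time
        (quality(gq=19, dp=10, cn=2.0), False, "i_genotype_quality"),
        (quality(gq=50, dp=3, cn=1.0), False, "ii_depth"),
        (quality(cn=2.5), False, "iii_copy_number"),
        (quality(dist=3), False, "iv_snp_distance"),
        # all boundaries exactly satisfied
        (quality(gq=20, dp=4, cn=2.0, dist=5), True, None),
        # dbSNP membership waives only the distance criterion
        (quality(dist=3, db=True), True, None),
        (quality(gq=19, db=True), False, "i_genotype_quality"),
    ])
    def test_criteria(self, q, passed, criterion):
        res = qc_snv(q, THR)
        assert res.passed is passed
        assert res.failed_criterion == criterion

    @pytest.mark.parametrize("field, value, passed", [
        ("genotype_quality", 19, False), ("genotype_quality", 20, True),
        ("genotype_quality", 21, True),
        ("depth", 3, False), ("depth", 4, True), ("depth", 5, True),
        ("copy_number", 1.99, True), ("copy_number", 2.0, True),
        ("copy_number", 2.01, False),
        ("nearest_snp_distance", 4, False),
        ("nearest_snp_distance", 5, True),
        ("nearest_snp_distance", 6, True),
    ])
    def test_threshold_boundaries(self, field, value, passed):
        q = quality()
        setattr(q, field, value)
        assert qc_snv(q, THR).passed is passed

    def test_first_failure_is_reported_in_order(self):
        q = quality(gq=0, dp=0, cn=9.0, dist=0)
        assert qc_snv(q, THR).failed_criterion == "i_genotype_quality"

    def test_missing_field_policy(self):
        q = quality(gq=None)
        assert qc_snv(q, THR).failed_criterion == "i_genotype_quality"
        assert qc_snv(q, THR, missing_policy="pass").passed
        # an unrecorded nearest-SNP distance never trips criterion (iv)
        assert qc_snv(quality(dist=None), THR).passed

    def test_accounting_partition(self):
        # pass count plus per-criterion failures must cover every input
        batch = [quality(gq=g, dp=d, cn=c, dist=s)
                 for g in (10, 30) for d in (2, 8)
                 for c in (1.0, 3.0) for s in (2, 50)]
        results = [qc_snv(q, THR) for q in batch]
        n_pass = sum(r.passed for r in results)
        by_criterion = {}
        for r in results:
            if not r.passed:
                by_criterion[r.failed_criterion] = \
                    by_criterion.get(r.failed_criterion, 0) + 1
        assert n_pass + sum(by_criterion.values()) == len(batch)

    def test_idempotent_and_deterministic(self):
        q = quality(gq=19)
        assert qc_snv(q, THR) == qc_snv(q, THR)


class TestIndelZygosity:
    @pytest.mark.parametrize("sup, tot, call", [
        (10, 20, "het"),        # mid-band
        (16, 20, "hom"),        # above band
        (14, 20, "het"),        # f = 0.70: upper bound is inside the band
        (6, 20, "het"),         # f = 0.30: lower bound inside the band
        (2, 20, "no_call"),     # below band
        (29, 100, "no_call"), (30, 100, "het"),
        (70, 100, "het"), (71, 100, "hom"),
    ])
    def test_banding(self, sup, tot, call):
        got, _ = call_indel_zygosity(IndelReadSupport(sup, tot), THR)
        assert got == call

    def test_zero_depth(self):
        call, reason = call_indel_zygosity(IndelReadSupport(0, 0), THR)
        assert call == "no_call" and reason == "zero-depth"

    @given(st.integers(1, 200), st.data())
    def test_partition_and_monotonicity(self, total, data):
        sup = data.draw(st.integers(0, total))
        call, _ = call_indel_zygosity(IndelReadSupport(sup, total), THR)
        assert call in ("no_call", "het", "hom")
        if sup < total:   # monotone: adding support never demotes the call
            nxt, _ = call_indel_zygosity(IndelReadSupport(sup + 1, total),
                                         THR)
            order = {"no_call": 0, "het": 1, "hom": 2}
            assert order[nxt] >= order[call]


# target restriction ---------------------------------------------------------

def _variant(pos, chrom="chr1"):
    site = VariantSite(chrom, pos, "A", "G")
    return VariantRecord(site=site,
                         genotypes={"s": GenotypeCall("s", "het")})


class TestTargetRestriction:
    TARGETS = {"chr1": [(1000, 2000)]}

    @pytest.mark.parametrize("pos, flank, kept", [
        (2150, 200, True),    # inside the 200 bp flank
        (2200, 200, True),    # flank endpoint inclusive
        (2201, 200, False),   # one past the flank
        (800, 200, True), (799, 200, False),
        (1000, 0, True), (2000, 0, True), (999, 0, False),
    ])
    def test_flank_boundaries(self, pos, flank, kept):
        kept_records, dropped = restrict_to_targets(
            [_variant(pos)], self.TARGETS, flank=flank)
        assert bool(kept_records) is kept
        assert dropped == (0 if kept else 1)

    def test_unknown_chromosome_dropped_with_warning(self, caplog):
        kept, dropped = restrict_to_targets([_variant(50, chrom="chrZ")],
                                            self.TARGETS, flank=0)
        assert kept == [] and dropped == 1

    @given(st.lists(st.integers(1, 5000), min_size=1, max_size=30),
           st.integers(0, 300), st.integers(0, 300))
    def test_subset_and_flank_monotonicity(self, positions, f1, f2):
        records = [_variant(p) for p in positions]
        lo, hi = sorted((f1, f2))
        kept_lo, _ = restrict_to_targets(records, self.TARGETS, flank=lo)
        kept_hi, _ = restrict_to_targets(records, self.TARGETS, flank=hi)
        keys = {r.key for r in records}
        assert {r.key for r in kept_lo} <= {r.key for r in kept_hi} <= keys
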