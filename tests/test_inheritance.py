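"""Dominant family filter, co-segregation checking and Mendelian screen."""

import itertools

import pytest

from _oracles import MENDEL_TABLE, oracle_trio_consistent
from famvar import (Pedigree, Sample, cosegregation_check,
                    dominant_shared_filter, mendelian_consistency)
from famvar.inheritance import CohortConfigError, trio_consistent

CASES = ["father", "daughter"]
CONTROLS = ["mother", "grandmother"]


def _genotypes(father="hom_ref", daughter="hom_ref", mother="hom_ref",
               grandmother="hom_ref"):
    return {"v": {"father": father, "daughter": daughter, "mother": mother,
                  "grandmother": grandmother}}


class TestDominantFilter:
    def test_shared_by_cases_absent_in_controls_is_kept(self):
        kept, _ = dominant_shared_filter(
            ["v"], _genotypes(father="het", daughter="het"),
            CASES, CONTROLS)
        assert kept == ["v"]

    def test_hom_alt_case_counts_as_carrying(self):
        kept, _ = dominant_shared_filter(
            ["v"], _genotypes(father="hom_alt", daughter="het"),
            CASES, CONTROLS)
        assert kept == ["v"]

    @pytest.mark.parametrize("gt", [
        _genotypes(father="het"),                             # not shared
        _genotypes(father="het", daughter="het", mother="het"),
        _genotypes(father="het", daughter="het",
                   grandmother="hom_alt"),                    # control carrier
    ])
    def test_unshared_or_control_carrier_dropped(self, gt):
        kept, _ = dominant_shared_filter(["v"], gt, CASES, CONTROLS)
        assert kept == []

    def test_empty_control_set_reduces_to_case_intersection(self):
        gt = {"v1": {"father": "het", "daughter": "het"},
              "v2": {"father": "het", "daughter": "hom_ref"}}
        kept, _ = dominant_shared_filter(["v1", "v2"], gt, CASES, [])
        assert kept == ["v1"]

    def test_empty_case_set_returns_nothing(self):
        kept, _ = dominant_shared_filter(
            ["v"], _genotypes(father="het", daughter="het"), [], CONTROLS)
        assert kept == []

    def test_missing_genotype_strict_vs_permissive(self):
        gt = _genotypes(father="het", daughter="het")
        gt["v"]["mother"] = "missing"
        strict, _ = dominant_shared_filter(["v"], gt, CASES, CONTROLS,
                                           missing="strict")
        assert strict == []
        kept, flagged = dominant_shared_filter(["v"], gt, CASES, CONTROLS,
                                               missing="permissive")
        assert kept == ["v"] and flagged == ["v"]

    def test_unknown_sample_is_config_error(self):
        with pytest.raises(CohortConfigError):
            dominant_shared_filter(["v"], _genotypes(), CASES + ["ghost"],
                                   CONTROLS)


# co-segregation -------------------------------------------------------------

def _relative_pedigree(n=10):
    ped = Pedigree()
    for i in range(n):
        ped.add_sample(Sample(f"rel{i:02d}", "unknown", "unaffected",
                              "relative"))
    return ped


class TestCosegregation:
    def test_single_carrier_fails_only_that_candidate(self):
        ped = _relative_pedigree()
        candidates = [f"v{i}" for i in range(22)]
        genotypes = {k: {f"rel{i:02d}": "hom_ref" for i in range(10)}
                     for k in candidates}
        genotypes["v7"]["rel03"] = "het"
        passing, failing = cosegregation_check(candidates, genotypes, ped)
        assert len(passing) == 21
        assert failing == {"v7": ["rel03"]}

    def test_partition_property(self):
        ped = _relative_pedigree()
        candidates = ["a", "b", "c"]
        genotypes = {"a": {"rel00": "het"}, "b": {"rel01": "hom_ref"},
                     "c": {}}
        passing, failing = cosegregation_check(candidates, genotypes, ped)
        assert sorted(passing + list(failing)) == sorted(candidates)
        assert not set(passing) & set(failing)

    def test_no_relatives_passes_vacuously_with_warning(self, caplog):
        passing, failing = cosegregation_check(
            ["a", "b"], {}, _relative_pedigree(0))
        assert passing == ["a", "b"] and failing == {}
        assert any("vacuous" in r.message for r in caplog.records)

    def test_multiple_carriers_all_reported(self):
        ped = _relative_pedigree()
        genotypes = {"v": {"rel00": "het", "rel04": "hom_alt",
                           "rel07": "het", "rel08": "hom_ref"}}
        _, failing = cosegregation_check(["v"], genotypes, ped)
        assert failing["v"] == ["rel00", "rel04", "rel07"]

    def test_affected_or_unknown_relatives_do_not_fail_candidates(self):
        ped = _relative_pedigree(2)
        ped.add_sample(Sample("aff", "unknown", "affected", "relative"))
        ped.add_sample(Sample("unk", "unknown", "unknown", "relative"))
        genotypes = {"v": {"aff": "het", "unk": "het", "rel00": "hom_ref"}}
        passing, failing = cosegregation_check(["v"], genotypes, ped)
        assert passing == ["v"] and failing == {}


# Mendelian screen -----------------------------------------------------------

GENOTYPES = ("hom_ref", "het", "hom_alt")


def test_exhaustive_trio_grid_matches_enumeration_oracles():
    """All 27 child x father x mother combinations agree with both the
    frozen transmission table and gamete enumeration."""
    for child, father, mother in itertools.product(GENOTYPES, repeat=3):
        got = trio_consistent(child, father, mother)
        assert got == (child in MENDEL_TABLE[(father, mother)])
        assert got == oracle_trio_consistent(child, father, mother)


def test_missing_genotype_is_never_a_violation():
    assert trio_consistent("missing", "hom_ref", "hom_ref")
    assert trio_consistent("hom_alt", "missing", "hom_ref")


def test_mendelian_consistency_over_pedigree():
    ped = Pedigree()
    ped.add_sample(Sample("f", "male", "affected"))
    ped.add_sample(Sample("m", "female", "unaffected"))
    ped.add_sample(Sample("c", "female", "affected"), father="f", mother="m")
    assert mendelian_consistency(
        {"f": "hom_ref", "m": "hom_ref", "c": "het"}, ped) == \
        {"c": "violation"}
    assert mendelian_consistency(
        {"f": "het", "m": "hom_ref", "c": "het"}, ped) == \
        {"c": "consistent"}
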