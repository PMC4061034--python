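"""Dominant-model family filtering and co-segregation checking.

The dominant filter keeps variants carried (het or hom-alt) by every
sequenced affected member and strictly absent (hom-ref) from every
sequenced unaffected member. Co-segregation then requires that no
unaffected relative genotyped in the validation round carries the
alternate allele; failures report the carrier ids. A Mendelian-consistency
screen over resolvable trios sanity-checks inputs and the simulator.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

from .core import Pedigree

logger = logging.getLogger("famvar")

_CARRIER = ("het", "hom_alt")


class CohortConfigError(ValueError):
    pass


def dominant_shared_filter(variant_keys: Sequence[str],
                           genotypes: Mapping[str, Mapping[str, str]],
                           cases: Sequence[str],
                           controls: Sequence[str],
                           missing: str = "strict",
                           ) -> tuple[list[str], list[str]]:
    """Keep variants het/hom-alt in ALL cases and hom-ref in ALL controls.

    ``genotypes`` maps variant key -> {sample: zygosity}. A genotype absent
    from the map counts as missing. Under ``missing="strict"`` (default) a
    missing genotype in any listed sample drops the variant; under
    ``"permissive"`` it is retained and flagged. Returns
    (retained keys, flagged keys).
    """
    if missing not in ("strict", "permissive"):
        raise ValueError(f"unknown missing policy {missing!r}")
    listed = list(cases) + list(controls)
    if variant_keys:
        seen = set()
        for gt in genotypes.values():
            seen.update(gt)
        absent = [s for s in listed if s not in seen]
        if absent:
            raise CohortConfigError(
                f"samples {absent} named as cases/controls have no "
                "genotypes in the cohort")
    retained: list[str] = []
    flagged: list[str] = []
    for key in variant_keys:
        if not cases:
            continue   # empty case set: nothing can be "shared by all cases"
        gt = genotypes.get(key, {})
        calls = {s: gt.get(s, "missing") for s in listed}
        has_missing = any(z == "missing" for z in calls.values())
        if has_missing and missing == "strict":
            continue
        # permissive mode judges only the non-missing genotypes
        ok_cases = all(calls[s] in _CARRIER
                       for s in cases if calls[s] != "missing")
        ok_controls = all(calls[s] == "hom_ref"
                          for s in controls if calls[s] != "missing")
        if ok_cases and ok_controls:
            retained.append(key)
            if has_missing:
                flagged.append(key)
    return retained, flagged


def cosegregation_check(candidates: Sequence[str],
                        relative_genotypes: Mapping[str, Mapping[str, str]],
                        pedigree: Pedigree,
                        ) -> tuple[list[str], dict[str, list[str]]]:
    """Check candidates against genotyped unaffected relatives.

    A candidate passes iff NO unaffected relative carries the alternate
    allele. Relatives with unknown affection are excluded from the check
    (logged). Returns (passing keys, {failing key: carrier ids}).
    """
    usable: list[str] = []
    for key in candidates:
        for rel in relative_genotypes.get(key, {}):
            if rel in usable:
                continue
            sample = pedigree.samples.get(rel)
            if sample is None or sample.affected == "unknown":
                logger.warning("relative %s has unknown affection status; "
                               "excluded from co-segregation", rel)
                continue
            if sample.affected == "unaffected":
                usable.append(rel)
    if not any(relative_genotypes.get(k) for k in candidates):
        logger.warning("no relative genotypes supplied: co-segregation "
                       "passes vacuously")
    passing: list[str] = []
    failing: dict[str, list[str]] = {}
    for key in candidates:
        carriers = sorted(
            rel for rel, zyg in relative_genotypes.get(key, {}).items()
            if rel in usable and zyg in _CARRIER)
        if carriers:
            failing[key] = carriers
        else:
            passing.append(key)
    return passing, failing


# Mendelian consistency ------------------------------------------------------

_ALLELE_SETS = {"hom_ref": ({0},), "het": ({0}, {1}), "hom_alt": ({1},)}


def _transmissible(parent_zyg: str) -> set[int]:
    """Alleles a parent of this zygosity can transmit (alt allele = 1)."""
    return {"hom_ref": {0}, "het": {0, 1}, "hom_alt": {1}}[parent_zyg]


def trio_consistent(child: str, father: str, mother: str) -> bool:
    """Is the child genotype possible given the parents' (biallelic site)?"""
    if "missing" in (child, father, mother):
        return True
    child_alleles = {"hom_ref": (0, 0), "het": (0, 1),
                     "hom_alt": (1, 1)}[child]
    fa, mo = _transmissible(father), _transmissible(mother)
    a, b = child_alleles
    return (a in fa and b in mo) or (b in fa and a in mo)


def mendelian_consistency(genotypes: Mapping[str, str], pedigree: Pedigree
                          ) -> dict[str, str]:
    """Per-trio consistency of one variant's genotypes.

    ``genotypes`` maps sample id -> zygosity. Returns
    {child id: "consistent" | "violation"} for every resolvable trio.
    """
    out = {}
    for child, father, mother in pedigree.trios():
        ok = trio_consistent(genotypes.get(child, "missing"),
                             genotypes.get(father, "missing"),
                             genotypes.get(mother, "missing"))
        out[child] = "consistent" if ok else "violation"
    return out
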