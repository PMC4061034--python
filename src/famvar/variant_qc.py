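"""Target-region restriction, the four SNP quality-control criteria, and
read-fraction indel zygosity calling.

A SNP is discarded if ANY of the four criteria holds:
(i) genotype quality < 20, (ii) depth < 4, (iii) estimated copy number > 2,
(iv) distance to the nearest SNP < 5 bp — with criterion (iv) waived for
SNPs present in dbSNP. Indels are genotyped from the fraction of
indel-supporting reads: 30-70 % heterozygous, > 70 % homozygous, below 30 %
no call (dropped downstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from intervaltree import IntervalTree

from .core import (IndelReadSupport, QCThresholds, SiteQuality, VariantRecord)

logger = logging.getLogger("famvar")

#: audit labels, in evaluation order
CRITERIA = ("i_genotype_quality", "ii_depth", "iii_copy_number",
            "iv_snp_distance")


@dataclass(frozen=True)
class QCResult:
    passed: bool
    failed_criterion: Optional[str] = None   # first failing criterion


def qc_snv(quality: SiteQuality, thresholds: QCThresholds = QCThresholds(),
           missing_policy: str = "fail") -> QCResult:
    """Evaluate the four SNP criteria; returns the first failure for the
    audit trail (evaluation order never changes pass/fail, only the label).

    ``missing_policy`` governs a field a criterion needs but is None:
    "fail" (default) fails that criterion, "pass" waives it.
    """
    if missing_policy not in ("fail", "pass"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    missing_fails = missing_policy == "fail"

    def check(value, predicate_fails) -> Optional[bool]:
        if value is None:
            return missing_fails
        return predicate_fails(value)

    t = thresholds
    tests = (
        ("i_genotype_quality",
         check(quality.genotype_quality, lambda v: v < t.min_genotype_quality)),
        ("ii_depth", check(quality.depth, lambda v: v < t.min_depth)),
        ("iii_copy_number",
         check(quality.copy_number, lambda v: v > t.max_copy_number)),
        # (iv) waived for SNPs present in dbSNP; an unknown distance means
        # no nearby SNP was recorded, which cannot trip the criterion
        ("iv_snp_distance",
         False if quality.in_dbsnp else (
             False if quality.nearest_snp_distance is None
             else quality.nearest_snp_distance < t.min_snp_distance_bp)),
    )
    for label, fails in tests:
        if fails:
            return QCResult(False, label)
    return QCResult(True)


def call_indel_zygosity(support: IndelReadSupport,
                        thresholds: QCThresholds = QCThresholds()
                        ) -> tuple[str, Optional[str]]:
    """Zygosity from the indel-supporting read fraction.

    Returns ("het" | "hom" | "no_call", reason). The het band is closed
    [lo, hi]; above it is homozygous; below it the variant is not called.
    """
    if support.total_reads == 0:
        return "no_call", "zero-depth"
    f = support.fraction
    if f > thresholds.het_fraction_hi:
        return "hom", None
    if f >= thresholds.het_fraction_lo:
        return "het", None
    return "no_call", "support-fraction below het band"


def build_target_index(targets: Mapping[str, Iterable[tuple[int, int]]],
                       flank: int = 200) -> dict[str, IntervalTree]:
    """Interval trees over 1-based inclusive targets expanded by ``flank``."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    index = {}
    for chrom, ivals in targets.items():
        tree = IntervalTree()
        for start, end in ivals:
            lo = max(1, start - flank)
            tree.addi(lo, end + flank + 1)   # tree is half-open
        tree.merge_overlaps()
        index[chrom] = tree
    return index


def restrict_to_targets(records: list[VariantRecord],
                        targets: Mapping[str, Iterable[tuple[int, int]]],
                        flank: int = 200,
                        ) -> tuple[list[VariantRecord], int]:
    """Keep variants inside any target interval expanded by ``flank`` bp on
    both sides; returns (survivors, number dropped)."""
    index = build_target_index(targets, flank)
    known_chroms = set(index)
    seen_unknown: set[str] = set()
    kept: list[VariantRecord] = []
    for rec in records:
        chrom = rec.site.chrom
        if chrom not in known_chroms:
            if chrom not in seen_unknown:
                logger.warning("no target intervals on %s; variants there "
                               "are dropped", chrom)
                seen_unknown.add(chrom)
            continue
        if index[chrom].overlaps_point(rec.site.pos):
            kept.append(rec)
    return kept, len(records) - len(kept)
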