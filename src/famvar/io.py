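"""Readers and writers for the standard formats the pipeline touches.

VCF 4.x is read with cyvcf2 and written with pysam; PED/FAM, BED and the
TSV side tables (annotations, population records, genotype panels,
transcript models) go through pandas. Coordinates are converted to 1-based
inclusive at this boundary (BED is 0-based half-open on disk).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml
from cyvcf2 import VCF

from .core import (ConsequenceAnnotation, GenotypeCall, IndelReadSupport,
                   Pedigree, PedigreeError, PopulationRecord, PredictorProfile,
                   Sample, SiteQuality, VariantRecord, VariantSite,
                   infer_vclass)

logger = logging.getLogger("famvar")

_INT_MISSING_FLOOR = -1  # cyvcf2 encodes missing ints as large negatives


@dataclass(frozen=True)
class FieldMap:
    """Maps the pipeline's quality fields onto VCF FORMAT/INFO keys.

    The upstream callers' native outputs do not share one tag dialect, so
    the mapping is configuration, not convention.
    """

    genotype_quality: str = "GQ"
    depth: str = "DP"
    copy_number: str = "CN"
    nearest_snp_distance: str = "SD"
    allele_depth: str = "AD"
    dbsnp_flag: str = "DB"   # INFO flag


class VcfConfigError(ValueError):
    """A configured FORMAT/INFO key does not exist in the VCF header."""


def _fmt_int(arr, i, col=0) -> Optional[int]:
    if arr is None:
        return None
    v = arr[i][col] if arr.ndim > 1 else arr[i]
    v = int(v)
    return None if v < _INT_MISSING_FLOOR + 1 and v < 0 else (v if v >= 0 else None)


def _fmt_float(arr, i) -> Optional[float]:
    if arr is None:
        return None
    v = float(arr[i][0] if arr.ndim > 1 else arr[i])
    return None if math.isnan(v) else v


def read_variants(path, field_map: FieldMap = FieldMap()
                  ) -> tuple[list[str], list[VariantRecord]]:
    """Read a VCF into decomposed biallelic :class:`VariantRecord` s.

    Every record yields one variant per alternate allele. Missing quality
    fields become ``None`` and are logged once per field, never silently
    defaulted.
    """
    vcf = VCF(str(path))
    header_keys = {h.info().get("ID") for h in vcf.header_iter()}
    for key in (field_map.genotype_quality, field_map.depth):
        if key not in header_keys:
            raise VcfConfigError(
                f"FORMAT key {key!r} from the field map is not declared in "
                f"the VCF header of {path}")
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    warned: set[str] = set()

    def warn_missing(field: str, where: str) -> None:
        if field not in warned:
            logger.warning("FORMAT/%s missing at %s; recorded as missing",
                           field, where)
            warned.add(field)

    for v in vcf:
        gq = v.format(field_map.genotype_quality)
        dp = v.format(field_map.depth)
        cn = (v.format(field_map.copy_number)
              if field_map.copy_number in header_keys else None)
        sd = (v.format(field_map.nearest_snp_distance)
              if field_map.nearest_snp_distance in header_keys else None)
        ad = (v.format(field_map.allele_depth)
              if field_map.allele_depth in header_keys else None)
        in_dbsnp = v.INFO.get(field_map.dbsnp_flag) is not None
        where = f"{v.CHROM}:{v.POS}"
        for alt_idx, alt in enumerate(v.ALT):
            try:
                site = VariantSite(v.CHROM, v.POS, v.REF, alt)
            except ValueError as exc:
                logger.warning("skipping unsupported allele at %s: %s",
                               where, exc)
                continue
            rec = VariantRecord(site=site)
            for i, sample in enumerate(samples):
                alleles = v.genotypes[i][:2]
                if any(a < 0 for a in alleles):
                    zyg = "missing"
                else:
                    n_alt = sum(1 for a in alleles if a == alt_idx + 1)
                    zyg = ("hom_ref", "het", "hom_alt")[n_alt]
                rec.genotypes[sample] = GenotypeCall(sample, zyg)
                q = SiteQuality(
                    genotype_quality=_fmt_int(gq, i),
                    depth=_fmt_int(dp, i),
                    copy_number=_fmt_float(cn, i),
                    nearest_snp_distance=_fmt_int(sd, i),
                    in_dbsnp=in_dbsnp,
                )
                if gq is None or q.genotype_quality is None:
                    warn_missing(field_map.genotype_quality, where)
                if dp is None or q.depth is None:
                    warn_missing(field_map.depth, where)
                rec.qualities[sample] = q
                if site.is_indel and ad is not None:
                    support = _fmt_int(ad, i, col=alt_idx + 1)
                    total = q.depth
                    if support is not None and total is not None:
                        rec.indel_support[sample] = IndelReadSupport(
                            supporting_reads=min(support, total),
                            total_reads=total)
            records.append(rec)
    return samples, records


def write_variants(samples: list[str], records: list[VariantRecord], path,
                   field_map: FieldMap = FieldMap()) -> None:
    """Write decomposed records back out as an uncompressed VCF."""
    import pysam

    header = pysam.VariantHeader()
    chroms: list[str] = []
    for r in records:
        if r.site.chrom not in chroms:
            chroms.append(r.site.chrom)
    for chrom in chroms:
        header.contigs.add(chrom, length=2_000_000_000)
    header.info.add(field_map.dbsnp_flag, 0, "Flag", "Site present in dbSNP")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add(field_map.genotype_quality, 1, "Integer",
                       "Phred genotype quality")
    header.formats.add(field_map.depth, 1, "Integer", "Read depth")
    header.formats.add(field_map.copy_number, 1, "Float",
                       "Estimated copy number")
    header.formats.add(field_map.nearest_snp_distance, 1, "Integer",
                       "Distance to nearest other SNP (bp)")
    header.formats.add(field_map.allele_depth, "R", "Integer",
                       "Reads supporting each allele")
    for s in samples:
        header.add_sample(s)

    gt_map = {"hom_ref": (0, 0), "het": (0, 1), "hom_alt": (1, 1),
              "missing": (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            rec = out.new_record(
                contig=r.site.chrom, start=r.site.pos - 1,
                alleles=(r.site.ref, r.site.alt))
            any_db = any(q.in_dbsnp for q in r.qualities.values())
            if any_db:
                rec.info[field_map.dbsnp_flag] = True
            for s in samples:
                fmt = rec.samples[s]
                g = r.genotypes.get(s)
                fmt["GT"] = gt_map[g.zygosity if g else "missing"]
                q = r.qualities.get(s)
                if q is not None:
                    if q.genotype_quality is not None:
                        fmt[field_map.genotype_quality] = q.genotype_quality
                    if q.depth is not None:
                        fmt[field_map.depth] = q.depth
                    if q.copy_number is not None:
                        fmt[field_map.copy_number] = q.copy_number
                    if q.nearest_snp_distance is not None:
                        fmt[field_map.nearest_snp_distance] = \
                            q.nearest_snp_distance
                sup = r.indel_support.get(s)
                if sup is not None:
                    fmt[field_map.allele_depth] = (
                        sup.total_reads - sup.supporting_reads,
                        sup.supporting_reads)
            out.write(rec)


# Pedigree -------------------------------------------------------------------

_PED_SEX = {"1": "male", "2": "female"}
_PED_AFF = {"1": "unaffected", "2": "affected"}


def read_pedigree(path, roles: Optional[Mapping[str, str]] = None) -> Pedigree:
    """Read a PLINK PED/FAM file (two-pass, so row order is free).

    ``roles`` optionally maps sample id -> pipeline role
    (exome_case / exome_control / relative / ...).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise PedigreeError(
                    f"{path}:{lineno}: expected >= 6 columns, got {len(parts)}")
            rows.append(parts[:6])
    ped = Pedigree()
    for _, sid, _, _, sex, aff in rows:
        role = (roles or {}).get(sid, "unassigned")
        ped.add_sample(Sample(
            id=sid,
            sex=_PED_SEX.get(sex, "unknown"),
            affected=_PED_AFF.get(aff, "unknown"),
            role=role))
    for _, sid, father, mother, _, _ in rows:   # second pass: links
        fa = None if father in ("0", "") else father
        mo = None if mother in ("0", "") else mother
        if fa or mo:
            ped.parents[sid] = (fa, mo)
    ped.validate()
    return ped


# BED targets ----------------------------------------------------------------

def read_targets(path) -> dict[str, list[tuple[int, int]]]:
    """BED (0-based half-open) -> {chrom: [(start, end)]} 1-based inclusive."""
    targets: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split()[:3]
            targets.setdefault(chrom, []).append((int(start) + 1, int(end)))
    for chrom in targets:
        targets[chrom].sort()
    return targets


def write_targets(targets: Mapping[str, list[tuple[int, int]]], path) -> None:
    with open(path, "w") as fh:
        for chrom in targets:
            for start, end in targets[chrom]:
                fh.write(f"{chrom}\t{start - 1}\t{end}\n")


# TSV side tables ------------------------------------------------------------

def _key(row) -> str:
    return f"{row['chrom']}:{int(row['pos'])}:{row['ref']}:{row['alt']}"


def read_population_table(path) -> dict[str, dict[str, PopulationRecord]]:
    """TSV (chrom, pos, ref, alt, db, present, af) -> {key: {db: record}}.

    Variants/databases without a row are treated as absent.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str,
                                            "alt": str})
    out: dict[str, dict[str, PopulationRecord]] = {}
    for _, row in df.iterrows():
        af = row.get("af")
        af = None if pd.isna(af) else float(af)
        rec = PopulationRecord(db=row["db"],
                               present=bool(row["present"]), af=af)
        out.setdefault(_key(row), {})[row["db"]] = rec
    return out


_PRED_DEFAULTS = {"sift": "missing", "mutation_taster": "missing",
                  "polyphen2": "missing", "pmut": "missing"}


def read_annotation_table(path) -> dict[str, tuple[ConsequenceAnnotation,
                                                   PredictorProfile]]:
    """TSV with the candidate-table schema (gene, consequence, codons,
    predictor calls, GERP) keyed by variant."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str,
                                            "alt": str})
    out = {}
    for _, row in df.iterrows():
        ann = ConsequenceAnnotation(
            gene=row["gene"],
            consequence=row["consequence"],
            codon_change=(None if pd.isna(row.get("codons")) else
                          str(row["codons"])),
            aa_change=(None if pd.isna(row.get("aa_change")) else
                       str(row["aa_change"])))
        calls = {}
        for col, default in _PRED_DEFAULTS.items():
            v = row.get(col)
            calls[col] = default if (v is None or pd.isna(v)) else str(v)
        gerp = row.get("gerp")
        profile = PredictorProfile(
            gerp=None if pd.isna(gerp) else float(gerp), **calls)
        out[_key(row)] = (ann, profile)
    return out


def read_genotype_table(path) -> tuple[dict[str, dict[str, str]],
                                       dict[str, str]]:
    """Long-format genotype TSV (chrom, pos, ref, alt, sample, zygosity
    [, group]) -> ({key: {sample: zygosity}}, {sample: group})."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str,
                                            "alt": str, "sample": str})
    genotypes: dict[str, dict[str, str]] = {}
    groups: dict[str, str] = {}
    for _, row in df.iterrows():
        genotypes.setdefault(_key(row), {})[row["sample"]] = row["zygosity"]
        if "group" in df.columns and not pd.isna(row["group"]):
            groups[row["sample"]] = row["group"]
    return genotypes, groups


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def candidate_table_path() -> Path:
    """Packaged 22-candidate annotation fixture (published study table)."""
    return Path(__file__).parent / "data" / "candidate_snvs.tsv"
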