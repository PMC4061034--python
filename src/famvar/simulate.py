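"""Synthetic pedigree-exome generator.

Emulates the study design the pipeline assumes: a sequenced quartet
(affected father and daughter; unaffected mother and paternal grandmother
as sequenced controls), ten genotyped unaffected relatives, and a sporadic
case / UC / healthy-control genotyping panel. One heterozygous causal
missense variant, absent from every reference database, is planted in the
two affecteds; everything else is a passenger drawn from a common/rare
allele-frequency mixture with Mendelian transmission through the pedigree,
per-field quality noise calibrated so roughly two thirds of raw calls pass
QC, and database membership that rises with allele frequency.

The allele-frequency spectrum is discretized onto small grids so that
:func:`expected_survivors` can state exact closed-form expectations (finite
sums over the generative classes) for every cascade stage; simulation
output is tested against those forms at a few standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import io as fio
from .core import (GenotypeCall, IndelReadSupport, Pedigree, PopulationRecord,
                   Sample, SiteQuality, VariantRecord, VariantSite)

QUARTET = ("daughter", "father", "grandmother", "mother")
CASES = ("daughter", "father")
CONTROLS = ("grandmother", "mother")

_BASES = "ACGT"

#: consequence mixes within the protein-disrupting / excluded classes
_PD_SNV = (("missense", 0.92), ("nonsense", 0.04), ("splice_site", 0.03),
           ("stoploss", 0.01))
_NPD_SNV = (("synonymous", 0.35), ("intronic", 0.35), ("utr", 0.15),
            ("intergenic", 0.15))
_PD_INDEL = (("frameshift", 0.8), ("inframe_indel", 0.2))
_NPD_INDEL = (("intronic", 0.6), ("utr", 0.2), ("intergenic", 0.2))


@dataclass
class CausalSpec:
    """The planted dominant variant: carried het by both affecteds, absent
    everywhere else, with a configurable predictor profile."""

    af: float = 0.001
    sift: str = "DAMAGING"
    mutation_taster: str = "disease_causing"
    polyphen2: str = "damaging"
    pmut: str = "pathological"
    gerp: float = 5.17
    panel_case_carriers: int = 1
    panel_control_carriers: int = 0


@dataclass
class SimulationConfig:
    """All generator dials. Defaults are the study conditions at desk scale
    (2,000 expected quality-passing-scale variants per sample; raising
    ``n_variants_per_sample`` to ~115,000 emulates full exome scale)."""

    seed: int = 0
    n_variants_per_sample: int = 2000
    frac_off_target: float = 0.02
    frac_indel: float = 0.06
    frac_common: float = 0.85
    common_af_grid: tuple = (0.05, 0.1, 0.2, 0.3, 0.5)
    rare_af_grid: tuple = (0.0005, 0.001, 0.002, 0.004)
    frac_protein_disrupting: float = 0.125
    # P(variant documented | class), per database
    db_presence: dict = field(default_factory=lambda: {
        "dbSNP": {"common": 0.95, "rare": 0.10},
        "KG1000": {"common": 0.75, "rare": 0.05},
        "HapMap": {"common": 0.40, "rare": 0.01},
    })
    ref_presence: dict = field(default_factory=lambda: {
        "EVS": {"common": 0.90, "rare": 0.02},
        "inhouse": {"common": 0.90, "rare": 0.02},
    })
    # marginal per-field QC failure fractions (SNVs)
    q_genotype_quality: float = 0.10
    q_depth: float = 0.10
    q_copy_number: float = 0.06
    q_snp_distance: float = 0.05
    # read-fraction model for indel genotyping
    indel_depth_grid: tuple = (16, 20, 30, 50)
    indel_het_support: float = 0.5
    indel_hom_support: float = 0.95
    n_relatives: int = 10
    panel_n_cases: int = 278
    panel_n_controls: int = 401
    panel_n_uc: int = 123
    af_reject_threshold: float = 0.005
    target_flank_bp: int = 200
    causal: CausalSpec = field(default_factory=CausalSpec)

    def validate(self) -> None:
        probs = [self.frac_off_target, self.frac_indel, self.frac_common,
                 self.frac_protein_disrupting, self.q_genotype_quality,
                 self.q_depth, self.q_copy_number, self.q_snp_distance,
                 self.indel_het_support, self.indel_hom_support]
        for d in (*self.db_presence.values(), *self.ref_presence.values()):
            probs.extend(d.values())
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if any(af <= self.af_reject_threshold for af in self.common_af_grid):
            raise ValueError("common AF grid must exceed the rejection "
                             "threshold (common variants are documented "
                             "above it)")
        if any(af > self.af_reject_threshold for af in self.rare_af_grid):
            raise ValueError("rare AF grid must not exceed the rejection "
                             "threshold")
        if not (0 < self.causal.af <= self.af_reject_threshold):
            raise ValueError("causal AF must be rare")
        if self.n_variants_per_sample < 10:
            raise ValueError("n_variants_per_sample too small to be useful")

    # -- analytic companions -------------------------------------------------

    def mean_carrier_prob(self) -> float:
        """Marginal P(a sample carries an alternate allele at a site)."""
        total = 0.0
        for w, af in self._af_mixture():
            total += w * (1.0 - (1.0 - af) ** 2)
        return total

    def n_sites(self) -> int:
        """Number of simulated sites so the expected per-sample called
        variant count hits ``n_variants_per_sample``."""
        return max(1, round(self.n_variants_per_sample
                            / self.mean_carrier_prob()))

    def _af_mixture(self) -> list[tuple[float, float]]:
        """[(weight, af)] over the discretized spectrum."""
        out = [(self.frac_common / len(self.common_af_grid), af)
               for af in self.common_af_grid]
        out += [((1 - self.frac_common) / len(self.rare_af_grid), af)
                for af in self.rare_af_grid]
        return out


# ---------------------------------------------------------------------------
# generation

def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    """Deterministic per-module substream of the master seed."""
    return np.random.default_rng([config.seed & 0x7FFFFFFF, stream])


def draw_founder_genotypes(rng: np.random.Generator, af, n: int | None = None
                           ) -> np.ndarray:
    """Hardy-Weinberg founder alt-allele doses (0/1/2).

    ``af`` may be a scalar (then ``n`` sites are drawn) or a per-site array.
    """
    if np.ndim(af) > 0:
        return rng.binomial(2, np.asarray(af))
    return rng.binomial(2, af, size=n)


def _transmit(rng: np.random.Generator, doses: np.ndarray) -> np.ndarray:
    """One gamete per site from a parent with the given alt dose."""
    return (rng.random(doses.shape) < doses / 2.0).astype(np.int8)


def _choice_mix(rng, n, mix) -> np.ndarray:
    labels = [m[0] for m in mix]
    p = np.array([m[1] for m in mix], dtype=float)
    return rng.choice(labels, size=n, p=p / p.sum())


_ZYG = np.array(["hom_ref", "het", "hom_alt"])


@dataclass
class Bundle:
    """The full simulated input set, usable in memory or written to disk."""

    config: SimulationConfig
    samples: list[str]
    records: list[VariantRecord]
    pedigree: Pedigree
    roles: dict[str, list[str]]
    targets: dict[str, list[tuple[int, int]]]
    annotations: dict
    popdb: dict
    panel_genotypes: dict[str, dict[str, str]]
    panel_groups: dict[str, str]
    relative_genotypes: dict[str, dict[str, str]]
    truth: pd.DataFrame

    @property
    def causal_key(self) -> str:
        return self.truth.loc[self.truth.is_causal, "key"].iloc[0]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fio.write_variants(self.samples, self.records,
                           outdir / "quartet.vcf")
        self._write_ped(outdir / "family.ped")
        fio.write_targets(self.targets, outdir / "targets.bed")
        self._annotation_frame().to_csv(outdir / "annotations.tsv",
                                        sep="\t", index=False)
        self._popdb_frame().to_csv(outdir / "popdb.tsv", sep="\t",
                                   index=False)
        self._genotype_frame(self.panel_genotypes, self.panel_groups).to_csv(
            outdir / "panel.tsv", sep="\t", index=False)
        self._genotype_frame(self.relative_genotypes).to_csv(
            outdir / "relatives.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        fio.dump_yaml(self.roles, outdir / "roles.yaml")
        cfg = asdict(self.config)
        for k in ("common_af_grid", "rare_af_grid", "indel_depth_grid"):
            cfg[k] = list(cfg[k])
        fio.dump_yaml(cfg, outdir / "sim_config.yaml")

    def _write_ped(self, path) -> None:
        aff = {"affected": "2", "unaffected": "1", "unknown": "0"}
        sex = {"male": "1", "female": "2", "unknown": "0"}
        with open(path, "w") as fh:
            for sid in sorted(self.pedigree.samples):
                s = self.pedigree.samples[sid]
                fa, mo = self.pedigree.parents.get(sid, (None, None))
                fh.write("\t".join(["FAMA", sid, fa or "0", mo or "0",
                                    sex[s.sex], aff[s.affected]]) + "\n")

    def _split_key(self, key: str) -> dict:
        chrom, pos, ref, alt = key.split(":")
        return {"chrom": chrom, "pos": int(pos), "ref": ref, "alt": alt}

    def _annotation_frame(self) -> pd.DataFrame:
        rows = []
        for key, (ann, prof) in self.annotations.items():
            rows.append({**self._split_key(key), "gene": ann.gene,
                         "consequence": ann.consequence,
                         "codons": ann.codon_change or "",
                         "aa_change": ann.aa_change or "",
                         "sift": prof.sift,
                         "mutation_taster": prof.mutation_taster,
                         "polyphen2": prof.polyphen2, "pmut": prof.pmut,
                         "gerp": "" if prof.gerp is None else prof.gerp})
        return pd.DataFrame(rows)

    def _popdb_frame(self) -> pd.DataFrame:
        rows = []
        for key, recs in self.popdb.items():
            for db, rec in recs.items():
                rows.append({**self._split_key(key), "db": db,
                             "present": rec.present,
                             "af": "" if rec.af is None else rec.af})
        return pd.DataFrame(rows,
                            columns=["chrom", "pos", "ref", "alt", "db",
                                     "present", "af"])

    def _genotype_frame(self, genotypes, groups=None) -> pd.DataFrame:
        rows = []
        for key, per_sample in genotypes.items():
            for sample, zyg in per_sample.items():
                row = {**self._split_key(key), "sample": sample,
                       "zygosity": zyg}
                if groups is not None:
                    row["group"] = groups.get(sample, "")
                rows.append(row)
        cols = ["chrom", "pos", "ref", "alt", "sample", "zygosity"]
        if groups is not None:
            cols.append("group")
        return pd.DataFrame(rows, columns=cols)

    @classmethod
    def load(cls, indir, config: Optional[SimulationConfig] = None
             ) -> "Bundle":
        indir = Path(indir)
        samples, records = fio.read_variants(indir / "quartet.vcf")
        roles = fio.load_yaml(indir / "roles.yaml")
        role_map = {}
        for role, ids in (("exome_case", roles.get("exome_cases", [])),
                          ("exome_control", roles.get("exome_controls", [])),
                          ("relative", roles.get("relatives", []))):
            for sid in ids:
                role_map[sid] = role
        pedigree = fio.read_pedigree(indir / "family.ped", roles=role_map)
        targets = fio.read_targets(indir / "targets.bed")
        annotations = fio.read_annotation_table(indir / "annotations.tsv")
        popdb = fio.read_population_table(indir / "popdb.tsv")
        panel_gt, panel_groups = fio.read_genotype_table(indir / "panel.tsv")
        rel_gt, _ = fio.read_genotype_table(indir / "relatives.tsv")
        truth_path = indir / "truth.tsv"
        truth = (pd.read_csv(truth_path, sep="\t")
                 if truth_path.exists() else pd.DataFrame())
        if config is None:
            cfg = fio.load_yaml(indir / "sim_config.yaml")
            cfg["causal"] = CausalSpec(**cfg["causal"])
            for k in ("common_af_grid", "rare_af_grid", "indel_depth_grid"):
                cfg[k] = tuple(cfg[k])
            config = SimulationConfig(**cfg)
        return cls(config=config, samples=samples, records=records,
                   pedigree=pedigree, roles=roles, targets=targets,
                   annotations=annotations, popdb=popdb,
                   panel_genotypes=panel_gt, panel_groups=panel_groups,
                   relative_genotypes=rel_gt, truth=truth)


def _build_pedigree(config: SimulationConfig) -> tuple[Pedigree, dict]:
    ped = Pedigree()
    ped.add_sample(Sample("grandmother", "female", "unaffected",
                          "exome_control"))
    ped.add_sample(Sample("mother", "female", "unaffected", "exome_control"))
    ped.add_sample(Sample("father", "male", "affected", "exome_case"),
                   mother="grandmother")
    ped.add_sample(Sample("daughter", "female", "affected", "exome_case"),
                   father="father", mother="mother")
    relatives = [f"rel{i + 1:02d}" for i in range(config.n_relatives)]
    for rid in relatives:
        ped.add_sample(Sample(rid, "unknown", "unaffected", "relative"))
    ped.validate()
    roles = {"exome_cases": list(CASES), "exome_controls": list(CONTROLS),
             "relatives": relatives}
    return ped, roles


def simulate_family_bundle(config: SimulationConfig) -> Bundle:
    """Generate the full input bundle plus its truth table."""
    config.validate()
    n = config.n_sites()
    thr = config.af_reject_threshold

    rng_site = _rng(config, 1)
    rng_geno = _rng(config, 2)
    rng_qual = _rng(config, 3)
    rng_db = _rng(config, 4)
    rng_panel = _rng(config, 5)

    # site-level attributes -------------------------------------------------
    is_common = rng_site.random(n) < config.frac_common
    af = np.where(is_common,
                  rng_site.choice(config.common_af_grid, size=n),
                  rng_site.choice(config.rare_af_grid, size=n))
    is_indel = rng_site.random(n) < config.frac_indel
    in_target = rng_site.random(n) >= config.frac_off_target
    is_pd = rng_site.random(n) < config.frac_protein_disrupting
    consequence = np.empty(n, dtype=object)
    for mask, mix in ((is_pd & ~is_indel, _PD_SNV),
                      (~is_pd & ~is_indel, _NPD_SNV),
                      (is_pd & is_indel, _PD_INDEL),
                      (~is_pd & is_indel, _NPD_INDEL)):
        k = int(mask.sum())
        if k:
            consequence[mask] = _choice_mix(rng_site, k, mix)

    # the plant: a rare on-target missense SNV, het in both affecteds
    causal_candidates = np.flatnonzero(~is_common & in_target & ~is_indel)
    if causal_candidates.size == 0:
        raise ValueError("no eligible site to plant the causal variant; "
                         "enlarge the simulation")
    ci = int(rng_site.choice(causal_candidates))
    af[ci] = config.causal.af
    is_pd[ci] = True
    consequence[ci] = "missense"

    # database membership ---------------------------------------------------
    class_col = np.where(is_common, "common", "rare")
    db_present: dict[str, np.ndarray] = {}
    for db, probs in config.db_presence.items():
        p = np.where(is_common, probs["common"], probs["rare"])
        db_present[db] = rng_db.random(n) < p
    db_present["YH"] = rng_db.random(n) < (1.0 - (1.0 - af) ** 2)
    ref_present: dict[str, np.ndarray] = {}
    for db, probs in config.ref_presence.items():
        p = np.where(is_common, probs["common"], probs["rare"])
        ref_present[db] = rng_db.random(n) < p
    for presence in (*db_present.values(), *ref_present.values()):
        presence[ci] = False

    # genotypes through the pedigree ----------------------------------------
    gm = draw_founder_genotypes(rng_geno, af, n)
    gf_hidden = draw_founder_genotypes(rng_geno, af, n)
    mo = draw_founder_genotypes(rng_geno, af, n)
    father = _transmit(rng_geno, gm) + _transmit(rng_geno, gf_hidden)
    daughter = _transmit(rng_geno, father) + _transmit(rng_geno, mo)
    rel_doses = {rid: draw_founder_genotypes(rng_geno, af, n)
                 for rid in (f"rel{i + 1:02d}"
                             for i in range(config.n_relatives))}
    doses = {"daughter": daughter, "father": father, "grandmother": gm,
             "mother": mo}
    for s in ("father", "daughter"):
        doses[s][ci] = 1
    for s in ("grandmother", "mother"):
        doses[s][ci] = 0
    for rid in rel_doses:
        rel_doses[rid][ci] = 0

    # quality fields --------------------------------------------------------
    quality: dict[str, dict[str, np.ndarray]] = {}
    for s in QUARTET:
        gq_fail = rng_qual.random(n) < config.q_genotype_quality
        dp_fail = rng_qual.random(n) < config.q_depth
        cn_fail = rng_qual.random(n) < config.q_copy_number
        sd_fail = rng_qual.random(n) < config.q_snp_distance
        for arr in (gq_fail, dp_fail, cn_fail, sd_fail):
            arr[ci] = False
        gq = np.where(gq_fail, rng_qual.integers(0, 20, n),
                      rng_qual.integers(20, 61, n))
        dp = np.where(dp_fail, rng_qual.integers(0, 4, n),
                      rng_qual.integers(4, 201, n))
        cn = np.round(np.where(cn_fail, rng_qual.uniform(2.05, 4.0, n),
                               rng_qual.uniform(0.8, 2.0, n)), 2)
        sd = np.where(sd_fail, rng_qual.integers(0, 5, n),
                      rng_qual.integers(5, 10_001, n))
        quality[s] = {"gq": gq, "dp": dp, "cn": cn, "sd": sd,
                      "fail": gq_fail | dp_fail | cn_fail
                              | (sd_fail & ~db_present["dbSNP"])}

    # indel read support (het/hom support fractions; low leakage on hom-ref)
    idepth = rng_qual.choice(config.indel_depth_grid, size=n)
    support: dict[str, np.ndarray] = {}
    for s in QUARTET:
        p_sup = np.select(
            [doses[s] == 1, doses[s] == 2],
            [config.indel_het_support, config.indel_hom_support], 0.01)
        support[s] = rng_qual.binomial(idepth, p_sup)

    # alleles, positions, genes ---------------------------------------------
    ref_idx = rng_site.integers(0, 4, n)
    alt_shift = rng_site.integers(1, 4, n)
    ins_extra = rng_site.integers(1, 4, n)
    del_or_ins = rng_site.random(n) < 0.5
    extra_bases = rng_site.integers(0, 4, (n, 3))

    chrom_idx = np.arange(n) % 22
    ordinal = np.arange(n) // 22
    per_chrom_max = ordinal[chrom_idx == 0].max() if n else 0
    target_start = 100_000
    target_end = 100_000 + 250 * int(per_chrom_max) + 50
    pos = np.where(in_target, target_start + ordinal * 250,
                   target_end + 10_000 + ordinal * 250)
    targets = {f"chr{c + 1}": [(target_start - 50, target_end)]
               for c in range(min(22, n))}

    order = np.lexsort((pos, chrom_idx))

    lo = 0.30   # het-band floor used for the truth table's recall outcome

    records: list[VariantRecord] = []
    keys = np.empty(n, dtype=object)
    annotations: dict = {}
    popdb: dict = {}
    genes = {}
    from .core import ConsequenceAnnotation, PredictorProfile

    # passenger predictor profiles (independent of causality)
    sift_has = rng_db.random(n) < 0.9
    sift_dam = rng_db.random(n) < 0.45
    mt_has = rng_db.random(n) < 0.9
    mt_dam = rng_db.random(n) < 0.5
    pp2_has = rng_db.random(n) < 0.5
    pp2_dam = rng_db.random(n) < 0.5
    pmut_has = rng_db.random(n) < 0.4
    pmut_dam = rng_db.random(n) < 0.5
    gerp = np.round(rng_db.uniform(-3.0, 6.0, n), 2)

    for i in order:
        chrom = f"chr{chrom_idx[i] + 1}"
        rb = _BASES[ref_idx[i]]
        if not is_indel[i]:
            ref, alt = rb, _BASES[(ref_idx[i] + alt_shift[i]) % 4]
        else:
            tail = "".join(_BASES[b] for b in
                           extra_bases[i][:ins_extra[i]])
            if del_or_ins[i]:
                ref, alt = rb + tail, rb
            else:
                ref, alt = rb, rb + tail
        site = VariantSite(chrom, int(pos[i]), ref, alt)
        keys[i] = site.key
        gene = f"GENE{i:05d}"
        genes[site.key] = gene
        rec = VariantRecord(site=site)
        for s in QUARTET:
            dose = int(doses[s][i])
            rec.genotypes[s] = GenotypeCall(s, str(_ZYG[dose]))
            q = quality[s]
            rec.qualities[s] = SiteQuality(
                genotype_quality=int(q["gq"][i]), depth=int(q["dp"][i]),
                copy_number=float(q["cn"][i]),
                nearest_snp_distance=int(q["sd"][i]),
                in_dbsnp=bool(db_present["dbSNP"][i]))
            if is_indel[i]:
                rec.qualities[s].depth = int(idepth[i])
                rec.indel_support[s] = IndelReadSupport(
                    supporting_reads=int(min(support[s][i], idepth[i])),
                    total_reads=int(idepth[i]))
        records.append(rec)

        if i == ci:
            c = config.causal
            profile = PredictorProfile(sift=c.sift,
                                       mutation_taster=c.mutation_taster,
                                       polyphen2=c.polyphen2, pmut=c.pmut,
                                       gerp=c.gerp)
        elif consequence[i] == "missense":
            profile = PredictorProfile(
                sift=("DAMAGING" if sift_dam[i] else "TOLERATED")
                if sift_has[i] else "missing",
                mutation_taster=("disease_causing" if mt_dam[i]
                                 else "polymorphism")
                if mt_has[i] else "missing",
                polyphen2=("damaging" if pp2_dam[i] else "benign")
                if pp2_has[i] else "missing",
                pmut=("pathological" if pmut_dam[i] else "neutral")
                if pmut_has[i] else "missing",
                gerp=float(gerp[i]))
        else:
            profile = PredictorProfile(gerp=float(gerp[i]))
        annotations[site.key] = (
            ConsequenceAnnotation(gene=gene, consequence=str(consequence[i])),
            profile)

        site_recs = {}
        for db in ("dbSNP", "KG1000", "HapMap"):
            if db_present[db][i]:
                site_recs[db] = PopulationRecord(db, True, float(af[i]))
        if db_present["YH"][i]:
            site_recs["YH"] = PopulationRecord("YH", True, None)
        for db in config.ref_presence:
            if ref_present[db][i]:
                site_recs[db] = PopulationRecord(db, True, None)
        if site_recs:
            popdb[site.key] = site_recs

    pedigree, roles = _build_pedigree(config)

    # realized fate at each filter stage (the truth table) -------------------
    carrier = {s: doses[s] > 0 for s in QUARTET}
    recall_ok = {}
    for s in QUARTET:
        need = np.ceil(lo * idepth - 1e-9)
        recall_ok[s] = np.where(carrier[s], support[s] >= need, True)
    qc_pass = {}
    for s in QUARTET:
        qc_pass[s] = np.where(is_indel, recall_ok[s], ~quality[s]["fail"])
    all_qc = np.logical_and.reduce([qc_pass[s] for s in QUARTET])
    db_rejected = ((db_present["dbSNP"] & (af > thr))
                   | (db_present["KG1000"] & (af > thr))
                   | (db_present["HapMap"] & (af > thr))
                   | db_present["YH"])
    dominant = (all_qc
                & carrier["father"] & carrier["daughter"]
                & ~carrier["mother"] & ~carrier["grandmother"])
    rel_carrier = np.zeros(n, dtype=bool)
    for rid, dose in rel_doses.items():
        rel_carrier |= dose > 0
    final = in_target & is_pd & ~db_rejected & dominant
    coseg = ~rel_carrier

    truth = pd.DataFrame({
        "key": keys, "chrom": [f"chr{c + 1}" for c in chrom_idx],
        "pos": pos, "af": af, "is_common": is_common,
        "is_indel": is_indel, "in_target": in_target,
        "consequence": consequence, "is_pd": is_pd,
        "db_rejected": db_rejected,
        **{f"dose_{s}": doses[s] for s in QUARTET},
        **{f"qc_pass_{s}": qc_pass[s] for s in QUARTET},
        "dominant_pass": dominant, "coseg_pass": coseg,
        "final_candidate": final,
        "is_causal": np.arange(n) == ci,
    }).iloc[order].reset_index(drop=True)

    # genotyped follow-up tables: relatives and the case/control panel -------
    key_index = {str(keys[i]): int(i) for i in range(n)}
    superset = [str(keys[i]) for i in order if final[i]]
    relative_genotypes = {
        key: {rid: str(_ZYG[int(rel_doses[rid][key_index[key]])])
              for rid in rel_doses}
        for key in superset}

    panel_samples = ([f"cd{i + 1:04d}" for i in range(config.panel_n_cases)]
                     + [f"hc{i + 1:04d}"
                        for i in range(config.panel_n_controls)]
                     + [f"uc{i + 1:04d}" for i in range(config.panel_n_uc)])
    panel_groups = {}
    for s in panel_samples:
        panel_groups[s] = {"cd": "case", "hc": "control",
                           "uc": "uc"}[s[:2]]
    panel_genotypes: dict[str, dict[str, str]] = {}
    causal_key = str(keys[ci])
    for key in superset:
        i = key_index[key]
        per: dict[str, str] = {}
        if key == causal_key:
            c = config.causal
            case_ids = [f"cd{j + 1:04d}" for j in
                        rng_panel.choice(config.panel_n_cases,
                                         size=c.panel_case_carriers,
                                         replace=False)]
            hc_ids = [f"hc{j + 1:04d}" for j in
                      rng_panel.choice(config.panel_n_controls,
                                       size=c.panel_control_carriers,
                                       replace=False)]
            for s in panel_samples:
                per[s] = "het" if s in case_ids + hc_ids else "hom_ref"
        else:
            dose = rng_panel.binomial(2, af[i], size=len(panel_samples))
            for s, d in zip(panel_samples, dose):
                per[s] = str(_ZYG[d])
        panel_genotypes[key] = per

    return Bundle(config=config, samples=list(QUARTET), records=records,
                  pedigree=pedigree, roles=roles, targets=targets,
                  annotations=annotations, popdb=popdb,
                  panel_genotypes=panel_genotypes, panel_groups=panel_groups,
                  relative_genotypes=relative_genotypes, truth=truth)


# ---------------------------------------------------------------------------
# analytic companions

def expected_count(n: int, retention_probs) -> float:
    """Product-rule expectation: n * prod(stage retention probabilities)."""
    return float(n * math.prod(retention_probs))


def _recall_prob(config: SimulationConfig, support_p: float,
                 lo: float = 0.30) -> float:
    """P(indel support fraction >= lo), averaged over the depth grid."""
    total = 0.0
    for d in config.indel_depth_grid:
        k = math.ceil(lo * d - 1e-9)
        total += float(stats.binom.sf(k - 1, d, support_p))
    return total / len(config.indel_depth_grid)


def dominant_quartet_prob(af: float) -> float:
    """P(father and daughter carry, mother and grandmother homozygous
    reference) under Hardy-Weinberg founders and Mendelian transmission.

    With both sequenced controls (mother; paternal grandmother) constrained
    to zero alt alleles, the father can only be heterozygous via the hidden
    grandfather (P = af marginally over his HWE genotype) and the daughter
    then inherits the alt allele with probability 1/2:
    (1-af)^4 * af * 1/2.
    """
    return (1.0 - af) ** 4 * af * 0.5


def expected_survivors(config: SimulationConfig
                       ) -> list[tuple[str, dict[str, tuple[float, float]]]]:
    """Exact per-stage expected survivor counts (and binomial SEs) under
    the generative model, mirroring the pipeline's cascade report labels.

    Per-sample streams are exchangeable, so one (mean, se) pair is reported
    per stage under the stream name "per_sample", plus "shared" for the
    dominant-model stage. The planted causal variant contributes +1
    deterministically to case streams; expectations here are for the
    passenger process plus that plant on the case streams (reported
    separately via the ``shared`` stream including the plant).
    """
    config.validate()
    n = config.n_sites()
    qc_base = ((1 - config.q_genotype_quality) * (1 - config.q_depth)
               * (1 - config.q_copy_number))
    r_het = _recall_prob(config, config.indel_het_support)
    r_hom = _recall_prob(config, config.indel_hom_support)
    thr = config.af_reject_threshold

    stage_names = [
        "total",
        "within target regions",
        "quality-passing",
        "protein-disrupting (PDSI)",
        "after filtering against dbSNP",
        "after filtering against dbSNP+KG1000",
        "after filtering against dbSNP+KG1000+HapMap",
        "after filtering against dbSNP+KG1000+HapMap+YH",
        "dominant model (shared by cases, absent in controls)",
    ]
    # accumulate per-site marginal probabilities per stage
    per_sample = np.zeros(len(stage_names) - 1)  # stages 0..7
    shared_p = 0.0

    for w_af, af in config._af_mixture():
        common = af > thr
        cls = "common" if common else "rare"
        q = 1.0 - (1.0 - af) ** 2
        p_yh_absent = (1.0 - af) ** 2
        for indel, w_ind in ((False, 1 - config.frac_indel),
                             (True, config.frac_indel)):
            for in_db, w_db in _branch(config.db_presence["dbSNP"][cls]):
                w = w_af * w_ind * w_db
                # per-sample carrier stream
                if indel:
                    p_het = 2 * af * (1 - af) / q
                    qc_carrier = p_het * r_het + (1 - p_het) * r_hom
                else:
                    dist_factor = 1.0 if in_db else \
                        (1 - config.q_snp_distance)
                    qc_carrier = qc_base * dist_factor
                # cascade retention factors
                f_dbsnp = 0.0 if (common and in_db) else 1.0
                f_kg = (1 - config.db_presence["KG1000"][cls]) if common \
                    else 1.0
                f_hm = (1 - config.db_presence["HapMap"][cls]) if common \
                    else 1.0
                f_yh = p_yh_absent
                cum = [
                    q,                                     # total
                    q * (1 - config.frac_off_target),      # in target
                ]
                cum.append(cum[-1] * qc_carrier)           # QC
                cum.append(cum[-1] * config.frac_protein_disrupting)
                cum.append(cum[-1] * f_dbsnp)
                cum.append(cum[-1] * f_kg)
                cum.append(cum[-1] * f_hm)
                cum.append(cum[-1] * f_yh)
                per_sample += w * np.array(cum)

                # shared dominant stream: father and daughter are both het
                # under the control constraint
                p_dom = dominant_quartet_prob(af)
                if indel:
                    qc_shared = r_het ** 2   # controls carry no indel reads
                else:
                    qc_shared = (qc_base * (1.0 if in_db else
                                            (1 - config.q_snp_distance))) ** 4
                shared_p += (w * (1 - config.frac_off_target)
                             * config.frac_protein_disrupting
                             * f_dbsnp * f_kg * f_hm * f_yh
                             * qc_shared * p_dom)

    out: list[tuple[str, dict[str, tuple[float, float]]]] = []
    for k, name in enumerate(stage_names[:-1]):
        p = per_sample[k]
        se = math.sqrt(n * p * (1 - p))
        # the plant adds +1 deterministically to the two case streams
        out.append((name, {"per_sample_case": (n * p + 1.0, se),
                           "per_sample_control": (n * p, se)}))
    mean = n * shared_p + 1.0
    se = math.sqrt(n * shared_p * (1 - shared_p))
    out.append((stage_names[-1], {"shared": (mean, se)}))
    return out


def _branch(p: float):
    return ((True, p), (False, 1.0 - p))
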