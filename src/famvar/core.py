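"""Domain types shared by every stage of the family-exome filtering pipeline.

The types here model one called variant and the evidence the filters consume:
site quality fields (genotype quality, depth, copy number, nearest-SNP
distance), per-sample zygosity, pedigree structure with affection status,
membership/frequency in reference population databases, and the functional
predictor profile (SIFT / MutationTaster / PolyPhen-2 / PMut calls plus a
GERP conservation score) used for candidate prioritization.

All coordinates are 1-based inclusive (VCF convention); BED inputs are
converted at the reader boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Optional

import pandas as pd

# Closed vocabularies -------------------------------------------------------

VARIANT_CLASSES = frozenset({"SNV", "insertion", "deletion"})
ZYGOSITIES = frozenset({"hom_ref", "het", "hom_alt", "missing"})
SEXES = frozenset({"male", "female", "unknown"})
AFFECTIONS = frozenset({"affected", "unaffected", "unknown"})
ROLES = frozenset({"exome_case", "exome_control", "relative", "panel_case",
                   "panel_control", "unassigned"})
DATABASES = frozenset({"dbSNP", "KG1000", "HapMap", "YH", "EVS", "inhouse"})

#: consequences that count as protein-disrupting (retained by the filter)
PROTEIN_DISRUPTING = frozenset({"missense", "nonsense", "stoploss",
                                "splice_site", "frameshift", "inframe_indel"})
#: consequences excluded as non-disrupting
NON_DISRUPTING = frozenset({"intergenic", "intronic", "utr", "synonymous",
                            "noncoding_in_gene"})
CONSEQUENCES = PROTEIN_DISRUPTING | NON_DISRUPTING

SIFT_CALLS = frozenset({"DAMAGING", "TOLERATED", "missing"})
MT_CALLS = frozenset({"disease_causing", "polymorphism", "missing"})
PP2_CALLS = frozenset({"damaging", "benign", "missing"})
PMUT_CALLS = frozenset({"pathological", "neutral", "missing"})


def infer_vclass(ref: str, alt: str) -> str:
    """Classify a biallelic ref/alt pair as SNV, insertion or deletion."""
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "insertion"
    if len(alt) < len(ref):
        return "deletion"
    raise ValueError(f"unsupported equal-length substitution {ref}>{alt}")


@dataclass(frozen=True)
class VariantSite:
    """One biallelic called variant (multi-allelic records are decomposed)."""

    chrom: str
    pos: int          # 1-based (VCF)
    ref: str
    alt: str
    vclass: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        vclass = self.vclass or infer_vclass(self.ref, self.alt)
        if vclass not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {vclass!r}")
        expected = infer_vclass(self.ref, self.alt)
        if vclass != expected:
            raise ValueError(
                f"vclass {vclass!r} inconsistent with alleles {self.ref}>{self.alt}")
        object.__setattr__(self, "vclass", vclass)

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_indel(self) -> bool:
        return self.vclass != "SNV"


@dataclass
class SiteQuality:
    """Per-genotype quality evidence consumed by the four SNP QC criteria.

    ``None`` encodes a missing field (reported, never silently defaulted).
    ``nearest_snp_distance`` may be None meaning "no nearby SNP known".
    """

    genotype_quality: Optional[int] = None
    depth: Optional[int] = None
    copy_number: Optional[float] = None
    nearest_snp_distance: Optional[int] = None
    in_dbsnp: bool = False

    def __post_init__(self):
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.genotype_quality is not None and self.genotype_quality < 0:
            raise ValueError("genotype_quality must be >= 0")


@dataclass(frozen=True)
class IndelReadSupport:
    """Read counts backing an indel call (zygosity from the support fraction)."""

    supporting_reads: int
    total_reads: int

    def __post_init__(self):
        if not (0 <= self.supporting_reads <= self.total_reads):
            raise ValueError(
                f"need 0 <= supporting ({self.supporting_reads}) <= total "
                f"({self.total_reads})")

    @property
    def fraction(self) -> float:
        if self.total_reads == 0:
            raise ZeroDivisionError("zero-depth indel support")
        return self.supporting_reads / self.total_reads


@dataclass(frozen=True)
class GenotypeCall:
    sample: str
    zygosity: str

    def __post_init__(self):
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")

    @property
    def is_carrier(self) -> bool:
        """Carries at least one alternate allele."""
        return self.zygosity in ("het", "hom_alt")


@dataclass
class Sample:
    id: str
    sex: str = "unknown"
    affected: str = "unknown"
    role: str = "unassigned"

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.affected not in AFFECTIONS:
            raise ValueError(f"unknown affection {self.affected!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, missing parent, bad sex)."""


@dataclass
class Pedigree:
    """Family structure: samples plus child -> (father, mother) links."""

    samples: dict[str, Sample] = field(default_factory=dict)
    parents: dict[str, tuple[Optional[str], Optional[str]]] = field(
        default_factory=dict)

    def add_sample(self, sample: Sample,
                   father: Optional[str] = None,
                   mother: Optional[str] = None) -> None:
        if sample.id in self.samples:
            raise PedigreeError(f"duplicate sample id {sample.id!r}")
        self.samples[sample.id] = sample
        if father or mother:
            self.parents[sample.id] = (father or None, mother or None)

    def validate(self) -> None:
        for child, (fa, mo) in self.parents.items():
            for pid, want_sex in ((fa, "male"), (mo, "female")):
                if pid is None:
                    continue
                if pid not in self.samples:
                    raise PedigreeError(
                        f"parent {pid!r} of {child!r} not in pedigree")
                sex = self.samples[pid].sex
                if sex not in ("unknown", want_sex):
                    raise PedigreeError(
                        f"parent {pid!r} of {child!r} has sex {sex}, "
                        f"expected {want_sex}")
        # acyclicity by DFS over parent links
        WHITE, GREY, BLACK = 0, 1, 2
        state = {sid: WHITE for sid in self.samples}

        def visit(sid: str) -> None:
            state[sid] = GREY
            for pid in self.parents.get(sid, (None, None)):
                if pid is None:
                    continue
                if state[pid] == GREY:
                    raise PedigreeError(f"parentage cycle through {pid!r}")
                if state[pid] == WHITE:
                    visit(pid)
            state[sid] = BLACK

        for sid in self.samples:
            if state[sid] == WHITE:
                visit(sid)

    def trios(self) -> list[tuple[str, str, str]]:
        """(child, father, mother) triples with both parents present."""
        out = []
        for child, (fa, mo) in sorted(self.parents.items()):
            if fa is not None and mo is not None:
                out.append((child, fa, mo))
        return out

    def ids_with(self, *, affected: Optional[str] = None,
                 role: Optional[str] = None) -> list[str]:
        out = []
        for sid, s in self.samples.items():
            if affected is not None and s.affected != affected:
                continue
            if role is not None and s.role != role:
                continue
            out.append(sid)
        return sorted(out)


@dataclass(frozen=True)
class PopulationRecord:
    """Presence (and frequency, when the database has one) of a variant in
    one reference population database."""

    db: str
    present: bool
    af: Optional[float] = None   # None = unknown

    def __post_init__(self):
        if self.db not in DATABASES:
            raise ValueError(f"unknown database {self.db!r}")
        if self.af is not None and not (0.0 <= self.af <= 1.0):
            raise ValueError(f"af {self.af} outside [0, 1]")
        if not self.present and self.af not in (None, 0.0):
            raise ValueError("absent record cannot carry a positive af")


@dataclass
class ConsequenceAnnotation:
    gene: str
    consequence: str
    codon_change: Optional[str] = None   # e.g. "ATC374ACC"
    aa_change: Optional[str] = None      # e.g. "p.I125T"

    def __post_init__(self):
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")


@dataclass
class PredictorProfile:
    """Functional-impact predictor calls plus GERP conservation score."""

    sift: str = "missing"
    mutation_taster: str = "missing"
    polyphen2: str = "missing"
    pmut: str = "missing"
    gerp: Optional[float] = None

    def __post_init__(self):
        for value, vocab, name in (
                (self.sift, SIFT_CALLS, "sift"),
                (self.mutation_taster, MT_CALLS, "mutation_taster"),
                (self.polyphen2, PP2_CALLS, "polyphen2"),
                (self.pmut, PMUT_CALLS, "pmut")):
            if value not in vocab:
                raise ValueError(f"unknown {name} call {value!r}")

    DAMAGING_CALLS = {
        "sift": "DAMAGING",
        "mutation_taster": "disease_causing",
        "polyphen2": "damaging",
        "pmut": "pathological",
    }

    def votes(self) -> tuple[int, int]:
        """(damaging votes, non-missing predictors)."""
        damaging = available = 0
        for name, dam in self.DAMAGING_CALLS.items():
            call = getattr(self, name)
            if call == "missing":
                continue
            available += 1
            if call == dam:
                damaging += 1
        return damaging, available


@dataclass
class QCThresholds:
    """All tunable filter thresholds, defaulting to the study's values."""

    min_genotype_quality: int = 20
    min_depth: int = 4
    max_copy_number: float = 2.0
    min_snp_distance_bp: int = 5
    af_reject_threshold: float = 0.005
    het_fraction_lo: float = 0.30
    het_fraction_hi: float = 0.70
    target_flank_bp: int = 200

    def __post_init__(self):
        if not (0 < self.het_fraction_lo < self.het_fraction_hi <= 1):
            raise ValueError("need 0 < het_fraction_lo < het_fraction_hi <= 1")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class CascadeReport:
    """Ordered per-stage survivor counts — the pipeline's audit trail.

    Each stage is (label, {stream name: count}); streams are per-sample
    variant streams or a single "shared" stream for family-level stages.
    """

    stages: list[tuple[str, dict[str, int]]] = field(default_factory=list)

    def add_stage(self, label: str, counts: Mapping[str, int]) -> None:
        counts = dict(counts)
        if any(c < 0 for c in counts.values()):
            raise ValueError(f"negative survivor count in stage {label!r}")
        self.stages.append((label, counts))

    def check_monotone(self) -> None:
        """Counts must never grow along a stream."""
        last: dict[str, int] = {}
        for label, counts in self.stages:
            for stream, count in counts.items():
                if stream in last and count > last[stream]:
                    raise ValueError(
                        f"stage {label!r}: stream {stream!r} grew "
                        f"({last[stream]} -> {count})")
                last[stream] = count

    def to_frame(self) -> pd.DataFrame:
        streams: list[str] = []
        for _, counts in self.stages:
            for s in counts:
                if s not in streams:
                    streams.append(s)
        rows = [{"stage": label, **{s: counts.get(s, "") for s in streams}}
                for label, counts in self.stages]
        return pd.DataFrame(rows, columns=["stage", *streams])


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Allele (or carrier) counts: a=case-alt, b=case-ref, c=control-alt,
    d=control-ref."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) totals."""
        return (self.a + self.b, self.c + self.d,
                self.a + self.c, self.b + self.d)


@dataclass
class VariantRecord:
    """One decomposed variant with everything the filters need, keyed by
    sample id for the per-genotype fields."""

    site: VariantSite
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)
    qualities: dict[str, SiteQuality] = field(default_factory=dict)
    indel_support: dict[str, IndelReadSupport] = field(default_factory=dict)

    @property
    def key(self) -> str:
        return self.site.key

    def carriers(self) -> list[str]:
        return sorted(s for s, g in self.genotypes.items() if g.is_carrier)


def genotype_matrix(records: Iterable[VariantRecord]) -> dict[str, dict[str, str]]:
    """{variant key: {sample: zygosity}} convenience view."""
    return {r.key: {s: g.zygosity for s, g in r.genotypes.items()}
            for r in records}
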