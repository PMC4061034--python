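"""Variant-consequence classification and the protein-disrupting filter.

Variants in intergenic, intronic and untranslated regions and synonymous
substitutions are excluded; missense, nonsense, stop-loss, splice-site
(within 2 bp of an internal CDS edge), frameshift and in-frame indels are
retained. A minimal transcript model (ordered CDS intervals plus the
spliced sense-strand CDS sequence) supports SNV classification by codon
translation; richer annotation sources can instead supply the consequence
column directly, in which case the provided column wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .core import (ConsequenceAnnotation, CONSEQUENCES, PROTEIN_DISRUPTING,
                   VariantRecord, VariantSite)

logger = logging.getLogger("famvar")


class AnnotationError(ValueError):
    pass


@dataclass
class TranscriptModel:
    """Minimal single-transcript gene model.

    ``cds_intervals`` are 1-based inclusive genomic intervals ordered 5'->3'
    (descending genomic coordinates on the minus strand); ``cds_sequence``
    is the spliced coding sequence on the sense strand.
    """

    gene: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    cds_sequence: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        length = sum(e - s + 1 for s, e in self.cds_intervals)
        if length != len(self.cds_sequence):
            raise ValueError(
                f"{self.gene}: CDS sequence length {len(self.cds_sequence)} "
                f"!= summed interval length {length}")
        if length % 3 != 0:
            raise ValueError(f"{self.gene}: CDS length {length} not a "
                             "multiple of 3")
        genomic = sorted(self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene}: overlapping CDS intervals")
        expect_desc = self.strand == "-"
        ordered = self.cds_intervals == sorted(
            self.cds_intervals, reverse=expect_desc)
        if not ordered:
            raise ValueError(f"{self.gene}: CDS intervals not ordered 5'->3'")
        self.cds_sequence = self.cds_sequence.upper()

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.cds_intervals]
        ends = [e for _, e in self.cds_intervals]
        return min(starts), max(ends)

    def cds_index(self, pos: int) -> int | None:
        """0-based index into the spliced CDS, or None if non-coding."""
        offset = 0
        for s, e in self.cds_intervals:
            if s <= pos <= e:
                if self.strand == "+":
                    return offset + (pos - s)
                return offset + (e - pos)
            offset += e - s + 1
        return None

    def internal_edges(self) -> list[int]:
        """Genomic coordinates of CDS boundaries that face an intron."""
        genomic = sorted(self.cds_intervals)
        edges = []
        for i, (s, e) in enumerate(genomic):
            if i > 0:
                edges.append(s)
            if i < len(genomic) - 1:
                edges.append(e)
        return edges


def classify_snv(variant: VariantSite, model: TranscriptModel,
                 splice_window: int = 2) -> ConsequenceAnnotation:
    """Classify a single-nucleotide variant against a transcript model.

    Outside the gene span -> intergenic; inside the span but non-coding and
    clear of splice edges -> noncoding_in_gene (UTR and intron are not
    distinguishable in this minimal model and are excluded either way);
    within ``splice_window`` bp of an internal CDS edge -> splice_site;
    inside the CDS the affected codon is translated with the standard code.
    """
    if variant.vclass != "SNV":
        raise ValueError("classify_snv handles SNVs only")
    if variant.chrom != model.chrom:
        return ConsequenceAnnotation(model.gene, "intergenic")
    lo, hi = model.span
    pos = variant.pos
    if pos < lo or pos > hi:
        return ConsequenceAnnotation(model.gene, "intergenic")
    idx = model.cds_index(pos)
    if idx is None:
        near_edge = any(abs(pos - edge) <= splice_window
                        for edge in model.internal_edges())
        label = "splice_site" if near_edge else "noncoding_in_gene"
        return ConsequenceAnnotation(model.gene, label)

    sense_ref = variant.ref if model.strand == "+" else \
        str(Seq(variant.ref).reverse_complement())
    sense_alt = variant.alt if model.strand == "+" else \
        str(Seq(variant.alt).reverse_complement())
    if model.cds_sequence[idx] != sense_ref:
        raise AnnotationError(
            f"{model.gene}: reference allele {variant.ref!r} at "
            f"{variant.chrom}:{pos} disagrees with model CDS base "
            f"{model.cds_sequence[idx]!r} (CDS position {idx + 1})")

    codon_start = (idx // 3) * 3
    ref_codon = model.cds_sequence[codon_start:codon_start + 3]
    within = idx - codon_start
    alt_codon = ref_codon[:within] + sense_alt + ref_codon[within + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        label = "synonymous"
    elif alt_aa == "*":
        label = "nonsense"
    elif ref_aa == "*":
        label = "stoploss"
    else:
        label = "missense"
    aa_pos = idx // 3 + 1
    return ConsequenceAnnotation(
        model.gene, label,
        codon_change=f"{ref_codon}{idx + 1}{alt_codon}",
        aa_change=f"p.{ref_aa}{aa_pos}{alt_aa}")


def filter_protein_disrupting(
        annotated: list[tuple[VariantRecord, ConsequenceAnnotation]]
        ) -> list[tuple[VariantRecord, ConsequenceAnnotation]]:
    """Keep exactly the protein-disrupting consequence classes."""
    unknown = sorted({ann.consequence for _, ann in annotated}
                     - CONSEQUENCES)
    if unknown:
        raise AnnotationError(f"unknown consequence labels: {unknown}")
    return [(rec, ann) for rec, ann in annotated
            if ann.consequence in PROTEIN_DISRUPTING]


def read_transcripts(path) -> list[TranscriptModel]:
    """6-column TSV: gene, chrom, strand, cds_starts, cds_ends, cds_sequence
    (starts/ends comma-separated, ordered 5'->3')."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    models = []
    for _, row in df.iterrows():
        starts = [int(x) for x in row["cds_starts"].split(",")]
        ends = [int(x) for x in row["cds_ends"].split(",")]
        models.append(TranscriptModel(
            gene=row["gene"], chrom=row["chrom"], strand=row["strand"],
            cds_intervals=list(zip(starts, ends)),
            cds_sequence=row["cds_sequence"]))
    return models
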