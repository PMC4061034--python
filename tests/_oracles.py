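"""Independent brute-force oracles used by the test suite.

Each oracle recomputes an operation's expected output by a different route
than the implementation (full-sequence mutation and translation, scipy
hypergeometric tail sums, explicit gamete enumeration) so the two paths
cross-check each other.
"""

from itertools import product

import numpy as np
from Bio.Seq import Seq
from scipy import stats


def oracle_classify_snv(pos, ref, alt, model, splice_window=2):
    """Consequence of a SNV by mutating the whole spliced CDS string and
    translating both proteins (independent of the per-codon implementation
    path)."""
    lo = min(s for s, _ in model.cds_intervals)
    hi = max(e for _, e in model.cds_intervals)
    if pos < lo or pos > hi:
        return "intergenic"
    # ordered genomic positions of the spliced CDS, 5'->3'
    cds_positions = []
    for s, e in model.cds_intervals:
        rng = range(s, e + 1) if model.strand == "+" else range(e, s - 1, -1)
        cds_positions.extend(rng)
    if pos not in cds_positions:
        genomic = sorted(model.cds_intervals)
        edges = []
        for i, (s, e) in enumerate(genomic):
            if i > 0:
                edges.append(s)
            if i < len(genomic) - 1:
                edges.append(e)
        if any(abs(pos - e) <= splice_window for e in edges):
            return "splice_site"
        return "noncoding_in_gene"
    idx = cds_positions.index(pos)
    sense_alt = alt if model.strand == "+" else \
        str(Seq(alt).reverse_complement())
    mutated = (model.cds_sequence[:idx] + sense_alt
               + model.cds_sequence[idx + 1:])
    ref_protein = str(Seq(model.cds_sequence).translate())
    alt_protein = str(Seq(mutated).translate())
    aa_idx = idx // 3
    ref_aa, alt_aa = ref_protein[aa_idx], alt_protein[aa_idx]
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "nonsense"
    if ref_aa == "*":
        return "stoploss"
    return "missense"


def genomic_base(model, pos):
    """The + strand reference base at a CDS genomic position."""
    cds_positions = []
    for s, e in model.cds_intervals:
        rng = range(s, e + 1) if model.strand == "+" else range(e, s - 1, -1)
        cds_positions.extend(rng)
    idx = cds_positions.index(pos)
    sense = model.cds_sequence[idx]
    return sense if model.strand == "+" else \
        str(Seq(sense).reverse_complement())


def oracle_fisher_two_sided(a, b, c, d):
    """Two-sided Fisher p via scipy's hypergeometric pmf over the full
    margin-fixed support."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom(n, r1, c1).pmf(support)
    obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= obs * (1 + 1e-9)].sum()))


#: child genotypes possible for each ordered pair of parent genotypes
MENDEL_TABLE = {
    ("hom_ref", "hom_ref"): {"hom_ref"},
    ("hom_ref", "het"): {"hom_ref", "het"},
    ("hom_ref", "hom_alt"): {"het"},
    ("het", "hom_ref"): {"hom_ref", "het"},
    ("het", "het"): {"hom_ref", "het", "hom_alt"},
    ("het", "hom_alt"): {"het", "hom_alt"},
    ("hom_alt", "hom_ref"): {"het"},
    ("hom_alt", "het"): {"het", "hom_alt"},
    ("hom_alt", "hom_alt"): {"hom_alt"},
}


def oracle_trio_consistent(child, father, mother):
    """Gamete-enumeration consistency check (independent of the allele-set
    implementation)."""
    alleles = {"hom_ref": (0, 0), "het": (0, 1), "hom_alt": (1, 1)}
    possible = set()
    for pa, ma in product(alleles[father], alleles[mother]):
        dose = pa + ma
        possible.add(("hom_ref", "het", "hom_alt")[dose])
    return child in possible
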