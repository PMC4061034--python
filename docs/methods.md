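# Methods

This note documents the models and procedures behind `famvar`: what each
filter assumes, what the synthetic-data generator emulates (and what it
does not), the numerical conventions, and the design choices made where
the workflow's published descriptions leave the design open.

## The filtering model

The pipeline targets the study design of a small dominant-disease family:
two affected members (here a father and daughter) and two unaffected
members (the proband's mother and wife — i.e. the affected child's
grandmother and mother) are exome-sequenced; additional unaffected
relatives and a sporadic case / healthy-control panel are genotyped for
validation. The underlying genetic model is a fully penetrant autosomal
dominant rare variant: every affected carries at least one alternate
allele, no unaffected family member carries any. No recessive,
compound-heterozygous, X-linked or reduced-penetrance model is
implemented; a variant carried by a healthy relative is simply removed,
which is the correct behaviour under full penetrance and the wrong one
under incomplete penetrance (a known limitation, deliberately not
papered over with a penetrance parameter that the workflow gives no way
to estimate).

### Quality control

The four SNP criteria (genotype quality < 20; depth < 4; copy number
> 2; nearest-SNP distance < 5 bp unless the site is in dbSNP) discard a
call if **any** criterion holds. They are evaluated in fixed order
(i)→(iv) and the first failure is recorded for the audit trail; the order
affects only that label, never the outcome (tested). The dbSNP exception
is attached to criterion (iv) only. A quality field that a criterion
needs but is missing fails that criterion by default
(`missing_policy="fail"`); the permissive alternative is available but
the strict default reflects that an unverifiable call should not anchor
a family-wide filter. An *unrecorded* nearest-SNP distance is treated as
"no nearby SNP known" and never trips criterion (iv).

Indels are genotyped from the fraction *f* of indel-supporting reads.
The heterozygous band is the **closed** interval [0.30, 0.70]; *f* > 0.70
is homozygous; *f* < 0.30 is a no-call and leaves that sample's stream.
Closing the band at both ends is the only reading consistent with "30–70 %"
and "> 70 %" side by side. The four SNP criteria are not applied to
indels, whose calling pipeline carries its own quality logic; a sequenced
control with no indel-supporting reads is accepted as homozygous
reference without further checks.

### Consequence classification

"Protein-disrupting" is operationalized as
{missense, nonsense, stop-loss, splice-site, frameshift, in-frame indel};
{intergenic, intronic, UTR, synonymous} are excluded. The built-in
classifier handles SNVs against a minimal transcript model (ordered CDS
intervals plus the spliced sense-strand CDS). It cannot distinguish UTR
from intron (both excluded), so in-gene non-coding positions collapse to
`noncoding_in_gene`. Splice sites are the ±2 bp around internal CDS
edges, the canonical donor/acceptor window. When an annotation column is
provided it wins over the classifier, because production annotation draws
on transcript databases this minimal model does not reimplement. Indel
consequences (frameshift vs in-frame) are always consumed from the
annotation source.

### Population-database cascade

dbSNP, 1000 Genomes and HapMap reject a variant when it is present with
a **known** allele frequency strictly above 0.5 % (a present record with
unknown frequency is indeterminate and retained, logged). YH is a single
personal genome and carries no population frequency, so presence alone
rejects — that is the only coherent reading of exempting YH from the
frequency condition without exempting it from the cascade. Because every
rejection is a per-variant predicate, the survivor set is invariant to
database order; only the intermediate counts in the report depend on it.
EVS and the in-house database are not part of the rejection cascade; they
feed the prioritization stage as occurrence annotations.

### Prioritization

The consensus score is
`damaging_votes / votes_available + bonus · [GERP ≥ threshold]`, with
`threshold = 4.0` and `bonus = 0.25` by default. Both are artifact
choices, documented as such: the GERP cutoff separates the strongly
constrained candidates in typical exome tables, and the bonus is chosen
so conservation can break vote ties but never outvote a predictor
majority. The ranking is a total order: defined scores before undefined
ones (all predictors missing), control-panel-negative first, then score,
then GERP, then gene symbol. This replaces web-service gene ranking,
which is neither reproducible offline nor specifiable; the package makes
no attempt to imitate any particular service's output.

### Association

The allelic test is the 1-df χ² on the 2×2 allele-count table without
continuity correction, matching the convention of PLINK's basic allelic
test. The Fisher companion enumerates the hypergeometric support exactly
(two-sided: sum of all table probabilities not exceeding the observed
one, with a 1e-9 relative tie tolerance; one-sided: the tail in the
observed direction). Odds ratios on tables with a zero cell use the
Haldane–Anscombe +0.5 correction and are flagged as corrected. The
association cohort folds the affected exome-sequenced carriers into the
case arm alongside the sporadic panel cases (`include_family_cases=True`);
with 278 sporadic cases, one sporadic carrier and the two familial
carriers against 401 carrier-free controls this yields the 3/560 vs 0/802
allele table, χ² = 4.31, p = 0.038 — the only documented carrier
accounting under which the sparse table reaches significance, and the
default for that reason. The sporadic-only table is one flag away.

## The synthetic-data generator

`simulate_family_bundle` draws, per site: a common/rare class
(P(common) = 0.85), an allele frequency from a small discrete grid
(common: {0.05, 0.1, 0.2, 0.3, 0.5}; rare: {5e-4, 1e-3, 2e-3, 4e-3}), an
indel flag (6 %), an off-target flag (2 %), a protein-disrupting flag
(12.5 %, the ratio seen between quality-passing and protein-disrupting
calls in real exome tables), database membership with class-dependent
probabilities (common variants are nearly always documented; YH presence
is 1−(1−af)², i.e. one diploid genome's carrier probability), founder
genotypes from Hardy–Weinberg, and non-founder genotypes by Mendelian
gamete transmission (the father descends from the genotyped grandmother
and an ungenotyped grandfather). Quality fields are drawn with per-field
failure fractions (GQ 0.10, depth 0.10, copy number 0.06, SNP distance
0.05) calibrated so roughly two thirds of raw calls pass QC, the
proportion seen in real exome summaries. Indel read support is
Binomial(depth, 0.5) for het and Binomial(depth, 0.95) for hom carriers
over a small depth grid — standard sampling models, stated here because
the workflow's published descriptions contain none.

One causal variant is planted: a rare on-target missense SNV, absent from
every database, heterozygous in both affecteds, homozygous reference in
both sequenced controls and all ten relatives, QC-clean, with a
configurable predictor profile (default: all four predictors damaging,
GERP 5.17) and a configurable number of planted panel carriers (default:
one sporadic case, no controls). Passenger predictor profiles are drawn
independently of everything else, so nothing but the truth table marks
the plant. All randomness flows from one seed through fixed per-module
substreams; identical seed and configuration give byte-identical bundles
and pipeline outputs.

`n_variants_per_sample` (default 2,000 at desk scale; ~115,000 emulates
full exome scale) is the *expected per-sample called-variant count*; the
number of simulated sites is derived from the mean carrier probability of
the AF mixture. The AF spectrum is discretized precisely so that
`expected_survivors` can state **exact** finite-sum expectations per
cascade stage: per-stream survivor counts are Binomial with a per-site
marginal retention probability computed by enumerating (AF class ×
indel × dbSNP-membership) branches, and the dominant-stage probability
has the closed form (1−af)⁴ · af · ½ (with both sequenced controls
constrained to zero alternate alleles, the father can be het only via the
hidden grandfather, and the daughter then inherits the allele with
probability ½) — verified in the tests against exhaustive enumeration
over founder genotypes and gametes.

What the generator does **not** emulate: linkage disequilibrium between
sites, read-level errors or mapping artefacts, relatedness among the ten
validation relatives (they are drawn as unlinked founders), population
stratification in the panel, and any correlation between predictor calls
and true pathogenicity of passengers. Passing tests therefore show that
the pipeline implements its stated rules and recovers a planted signal
under those rules — not that the rules themselves are well calibrated on
real cohorts.

## Numerical conventions and degenerate inputs

Coordinates are 1-based inclusive everywhere; BED input is converted at
the reader boundary. Multi-allelic VCF records are decomposed into
biallelic variants before any filtering; a genotype carrying a different
alternate allele counts as non-carrier for the variant under test. All
frequency and fraction comparisons use the strict/closed senses stated
above (AF rejection strictly > 0.005; het band closed). Zero-depth indel
support is a no-call with an explicit reason; a zero margin makes the χ²
test inapplicable (reported as missing with a reason) rather than zero or
one; an empty panel arm skips the test; an empty case set makes the
dominant filter return the empty set; co-segregation with no genotyped
relatives passes vacuously with a warning. Missing quality fields are
reported, never silently defaulted.

## Test-scale choices

The default suite runs the generator at 2,000 expected variants per
sample and the parameter-recovery study over 50 seeds at that scale —
sizes chosen so the whole suite exercises every stage, keeps the
binomial standard errors tight enough for 4-SE calibration checks, and
finishes in about a minute and a half. The Fisher oracle-equivalence
check enumerates every 2×2 table with N ≤ 60 (~6×10⁵ tables). For the
per-run calibration assertions, individual stage counts are required to
sit inside the 4-SE band in ≥ 99 % of comparisons and the 50-run mean
within 4 SE/√m of each closed form: with ~1,800 small Poisson-tailed
counts, demanding literally zero excursions from a normal-theory band
would fail by chance even for a correct generator.
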