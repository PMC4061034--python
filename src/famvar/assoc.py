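"""Case-control validation statistics.

Panel screening counts carriers and alternate alleles; the allelic
chi-square test is the classic 1-df test on the 2x2 allele-count table
without continuity correction (the convention of PLINK's basic allelic
association test); a Fisher exact companion handles sparse tables by
direct hypergeometric enumeration. The odds ratio falls back to the
Haldane-Anscombe +0.5 correction when a cell is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

from scipy import stats

from .core import ContingencyTable2x2


@dataclass(frozen=True)
class PanelCounts:
    """Carrier and allele accounting from a genotyped case/control panel."""

    case_carriers: int
    control_carriers: int
    case_alt_alleles: int
    case_total_alleles: int
    control_alt_alleles: int
    control_total_alleles: int
    n_missing: int

    @property
    def degenerate(self) -> bool:
        return self.case_total_alleles == 0 or self.control_total_alleles == 0

    def allele_table(self) -> ContingencyTable2x2:
        return ContingencyTable2x2(
            a=self.case_alt_alleles,
            b=self.case_total_alleles - self.case_alt_alleles,
            c=self.control_alt_alleles,
            d=self.control_total_alleles - self.control_alt_alleles)


_ALT_DOSE = {"hom_ref": 0, "het": 1, "hom_alt": 2}


def screen_panel(genotypes: Mapping[str, str],
                 groups: Mapping[str, str]) -> PanelCounts:
    """Count carriers and alternate alleles among panel cases and controls.

    ``groups`` maps sample -> {"case", "control"} (other labels, e.g. a
    separate disease arm, are ignored). Missing genotypes are excluded from
    the denominators and reported in ``n_missing``.
    """
    counts = {"case": [0, 0, 0], "control": [0, 0, 0]}  # carriers, alt, total
    n_missing = 0
    for sample, zyg in genotypes.items():
        group = groups.get(sample)
        if group not in counts:
            continue
        if zyg == "missing":
            n_missing += 1
            continue
        dose = _ALT_DOSE[zyg]
        counts[group][0] += int(dose > 0)
        counts[group][1] += dose
        counts[group][2] += 2
    return PanelCounts(
        case_carriers=counts["case"][0],
        control_carriers=counts["control"][0],
        case_alt_alleles=counts["case"][1],
        case_total_alleles=counts["case"][2],
        control_alt_alleles=counts["control"][1],
        control_total_alleles=counts["control"][2],
        n_missing=n_missing)


@dataclass(frozen=True)
class AssocResult:
    chi2: Optional[float]
    df: int
    p: Optional[float]
    odds_ratio: Optional[float]
    or_corrected: bool = False
    reason: Optional[str] = None


def odds_ratio(t: ContingencyTable2x2) -> tuple[Optional[float], bool]:
    """ad/bc, with the Haldane-Anscombe +0.5 correction on any zero cell."""
    if 0 in (t.a, t.b, t.c, t.d):
        a, b, c, d = (x + 0.5 for x in (t.a, t.b, t.c, t.d))
        return (a * d) / (b * c), True
    return (t.a * t.d) / (t.b * t.c), False


def allelic_chisq(t: ContingencyTable2x2) -> AssocResult:
    """1-df chi-square on the allele-count table, no continuity correction.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); any zero margin makes
    the test inapplicable (p reported as missing with a reason).
    """
    r1, r2, c1, c2 = t.margins
    if 0 in (r1, r2, c1, c2):
        orat, corr = odds_ratio(t)
        return AssocResult(None, 1, None, orat, corr,
                           reason="zero margin: test not applicable")
    num = t.n * (t.a * t.d - t.b * t.c) ** 2
    chi2 = num / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    orat, corr = odds_ratio(t)
    return AssocResult(chi2, 1, p, orat, corr)


def fisher_exact(t: ContingencyTable2x2, sided: str = "two") -> float:
    """Fisher's exact test by hypergeometric enumeration over all tables
    with the observed margins.

    One-sided: the tail in the direction of the observed deviation of the
    a-cell (the smaller of the upper and lower tails). Two-sided: sum of
    probabilities of all tables no more probable than the observed one.
    """
    if sided not in ("one", "two"):
        raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")
    r1, _, c1, _ = t.margins
    n = t.n
    # support of the a-cell given fixed margins
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    denom = math.comb(n, c1)
    pmf = [math.comb(r1, a) * math.comb(n - r1, c1 - a) / denom
           for a in range(lo, hi + 1)]
    obs = t.a - lo
    if sided == "one":
        return min(1.0, sum(pmf[obs:]), sum(pmf[:obs + 1]))
    cutoff = pmf[obs] * (1 + 1e-9)   # tolerate roundoff at ties
    return min(1.0, sum(p for p in pmf if p <= cutoff))
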