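"""Exercise the four SNP quality-control criteria and indel banding.

Shows which criterion fires first for a few genotype-quality profiles and
how the indel-supporting read fraction maps onto het / hom / no-call.
"""

from famvar import (IndelReadSupport, QCThresholds, SiteQuality,
                    call_indel_zygosity, qc_snv)

thresholds = QCThresholds()   # GQ>=20, depth>=4, CN<=2, distance>=5 bp

profiles = {
    "clean call": SiteQuality(50, 30, 1.5, 100, in_dbsnp=False),
    "low genotype quality": SiteQuality(19, 10, 2.0, 100, in_dbsnp=False),
    "shallow coverage": SiteQuality(50, 3, 1.0, 100, in_dbsnp=False),
    "clustered, novel": SiteQuality(50, 30, 2.0, 3, in_dbsnp=False),
    "clustered, in dbSNP": SiteQuality(50, 30, 2.0, 3, in_dbsnp=True),
}
for name, quality in profiles.items():
    res = qc_snv(quality, thresholds)
    verdict = "pass" if res.passed else f"fail({res.failed_criterion})"
    print(f"{name:24s} -> {verdict}")

print()
for supporting in (2, 6, 10, 14, 16):
    call, _ = call_indel_zygosity(IndelReadSupport(supporting, 20),
                                  thresholds)
    print(f"indel support {supporting:>2d}/20 (f={supporting / 20:.2f}) "
          f"-> {call}")
# A clustered novel SNP fails criterion (iv), but dbSNP membership waives
# exactly that criterion; the indel het band is the closed interval
# [0.30, 0.70] of supporting reads, above it homozygous, below it no call.
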