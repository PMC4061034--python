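"""Case-control validation of a single candidate variant.

Reconstructs the carrier accounting of a rare-variant validation round:
280 CD cases (278 sporadic plus the 2 exome-sequenced familial carriers)
against 401 healthy controls, with 3 heterozygous carriers among the
cases and none among the controls. Runs the allelic chi-square test (the
convention of PLINK's basic allelic association test) and the Fisher
exact companion on the carrier table.
"""

from famvar import (ContingencyTable2x2, allelic_chisq, fisher_exact,
                    screen_panel)

# genotyped panel: 3 het carriers among 280 cases, none among 401 controls
genotypes = {f"cd{i:04d}": ("het" if i < 3 else "hom_ref")
             for i in range(280)}
genotypes.update({f"hc{i:04d}": "hom_ref" for i in range(401)})
groups = {s: ("case" if s.startswith("cd") else "control")
          for s in genotypes}

counts = screen_panel(genotypes, groups)
alleles = counts.allele_table()
print(f"case carriers {counts.case_carriers}/280, "
      f"control carriers {counts.control_carriers}/401")
print(f"allele table: {alleles.a}/{alleles.a + alleles.b} case alt vs "
      f"{alleles.c}/{alleles.c + alleles.d} control alt")

res = allelic_chisq(alleles)
print(f"allelic chi2 = {res.chi2:.3f} (1 df), p = {res.p:.4f}, "
      f"OR = {res.odds_ratio:.2f} (0-cell corrected)")

carrier_table = ContingencyTable2x2(3, 277, 0, 401)
print(f"Fisher exact on the carrier table: "
      f"p = {fisher_exact(carrier_table):.4f}")
# The allelic test crosses p < 0.05 (p ~ 0.038); the sparser genotypic
# Fisher test is suggestive (p ~ 0.069) — exactly the regime where a
# single extra carrier decides significance.
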