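"""Co-segregation of validated candidates in unaffected relatives.

Encodes the validation round of a dominant family study: 22 candidate
variants checked by direct sequencing in 10 unaffected relatives, with the
KLF4 variant found in exactly one of them. A candidate co-segregates only
if no unaffected relative carries the alternate allele.
"""

from famvar import Pedigree, Sample, cosegregation_check
from famvar.io import candidate_table_path, read_annotation_table

table = read_annotation_table(candidate_table_path())
candidates = list(table)
klf4 = next(k for k, (ann, _) in table.items() if ann.gene == "KLF4")

relatives = [f"rel{i:02d}" for i in range(10)]
pedigree = Pedigree()
for rid in relatives:
    pedigree.add_sample(Sample(rid, "unknown", "unaffected", "relative"))

genotypes = {k: {r: "hom_ref" for r in relatives} for k in candidates}
genotypes[klf4]["rel03"] = "het"      # the one healthy carrier

passing, failing = cosegregation_check(candidates, genotypes, pedigree)
print(f"{len(passing)} of {len(candidates)} candidates co-segregate")
for key, carriers in failing.items():
    gene = table[key][0].gene
    print(f"broken by a healthy carrier: {gene} ({key}) "
          f"carried by {', '.join(carriers)}")
# 21/22: one healthy carrier is enough to break co-segregation under a
# fully penetrant dominant model, removing that candidate.
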