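"""Score a call set against truth with confusion-matrix metrics.

Uses the genotype confusion matrix C_tp (true genotype t, predicted p).
True positives tolerate het/hom swaps: TPN = C11 + C22 + C12 + C21;
sensitivity = TPN / (TPN + C10 + C20); FDR = (C01+C02) / (TPN+C01+C02).
"""

from alucall.evaluate import (ConfusionMatrix, confusion, fdr,
                              match_by_locus, mendelian_violations,
                              metrics_table, sensitivity)

# metrics from explicit counts
cm = ConfusionMatrix.from_counts(c11=3_521, c22=3_342, c10=132, c01=12,
                                 c21=82)
print(f"sensitivity {100 * sensitivity(cm):.1f}%  "
      f"FDR {100 * fdr(cm):.1f}%  (from raw counts)")

# metrics from matched truth/predicted genotype maps
truth = {("s1", "alu1"): "G1", ("s1", "alu2"): "G2", ("s2", "alu1"): "G0"}
predicted = {("s1", "alu1"): "G1", ("s2", "alu1"): "G1"}  # one false positive
cm = confusion(match_by_locus(truth, predicted))
print(metrics_table({"toy": cm}), end="")

# Mendelian consistency of a trio call set
father = {"alu1": "G1", "alu2": "G0"}
mother = {"alu1": "G0", "alu2": "G0"}
child = {"alu1": "G2", "alu2": "G1"}  # both impossible given the parents
count, loci, bound = mendelian_violations(father, mother, child)
print(f"trio violations: {count} at {loci}; implied FDR lower bound "
      f"{100 * bound:.0f}% of child carrier calls")
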