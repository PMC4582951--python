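"""Genotype annotated Alu elements for deletions in every individual.

Runs on the population written by 01_simulate_population.py. For each
annotated Alu the caller classifies read pairs into internal (I), split
(S) and spanning (A) evidence and reports the maximum-likelihood diploid
genotype: G0 = Alu present on both haplotypes (reference-like), G1 =
heterozygous deletion, G2 = Alu absent from both haplotypes.
"""

import glob

from alucall.deletion import call_deletions
from alucall.loci import read_alu_bed
from alucall.vcfio import write_deletion_vcf

loci = read_alu_bed("example_simdel/targets.bed")
bams = sorted(glob.glob("example_simdel/bam/*.bam"))
samples, calls = call_deletions("example_simdel/reference.fa", bams, loci)

print(f"{len(loci)} loci x {len(samples)} samples")
for loc in loci:
    row = " ".join(f"{c.genotype or './.'}" for c in calls[loc.name])
    print(f"{loc.name:12s} {row}")
print("columns:", " ".join(samples))
print("(each call is the argmax of the three genotype log-likelihoods;"
      " quality and I/S/A evidence counts go into the VCF)")

write_deletion_vcf("example_simdel/deletions.vcf", loci, samples, calls,
                   {"chr1": 999_999_999})
print("wrote example_simdel/deletions.vcf")
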