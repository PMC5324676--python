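"""Translate diplotype strings into activity scores and metabolizer groups.

The activity-score model sums each allele's enzyme-activity contribution
over all gene copies (an XN suffix counts as two copies): normal-function
alleles contribute 1, reduced-function 0.5, null alleles and the whole-gene
deletion *5 contribute 0.  Fixed cut-points then translate the score:
0 -> poor, (0, 1.5] -> intermediate, (1.5, 2.5) -> normal,
>= 2.5 -> ultrarapid.
"""

from amplistar.fixtures import fixture_table
from amplistar.starcall import predict_phenotype_from_string

activities = fixture_table().activities()

for genotype in ["*1/*35A", "*1/*41", "*4A/*5", "*10D/*10D", "*9/*41XN", "*2A/*2AXN"]:
    phenotype, score = predict_phenotype_from_string(genotype, activities)
    print(f"{genotype:>12}  activity score {score:>4.1f}  ->  {phenotype}")

print()
print("*1/*41 and *9/*41XN both land exactly on the 1.5 boundary, which the")
print("cut-points place in the intermediate group; a duplicated normal-")
print("function allele (*2AXN) pushes the score to 3 and the ultrarapid group.")
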