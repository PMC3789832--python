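"""Spore-viability statistics and Fisher contrasts between strains.

Builds viability-class distributions for the smt3-deletion heterozygote
control and the SUMO-diminished strain from their dissection counts,
recomputes overall spore viability, and tests whether the 2-spore-viable
fraction differs between them.
"""

from tetramap import (
    ViabilityDistribution,
    compare_viability_classes,
    spore_viability_percent,
    sporulation_efficiency,
)

# tetrads by number of viable spores (4, 3, 2, 1, 0)
control = ViabilityDistribution(counts={4: 1, 3: 4, 2: 280, 1: 25, 0: 3})
diminished = ViabilityDistribution(counts={4: 6, 3: 1, 2: 435, 1: 74, 0: 21})

for name, dist in [("smt3/+ control", control), ("SUMO-diminished", diminished)]:
    res = spore_viability_percent(dist)
    print(f"{name}: {dist.total_tetrads} tetrads, "
          f"spore viability {res.raw:.1f}% (printed as {res.rounded}%)")
# A strain heterozygous for the haploid-lethal smt3 deletion cannot exceed
# 50% viability: two spores of every tetrad inherit the lethal allele.

table, p = compare_viability_classes(control, diminished, classes={2})
print(f"\n2-spore-viable contrast: {table.rows}, two-sided Fisher p = {p:.4f}")
table, p = compare_viability_classes(control, diminished, classes={0, 1})
print(f"0+1-spore-viable contrast: {table.rows}, two-sided Fisher p = {p:.4f}")
# p < 0.01 in both: the SUMO-diminished strain loses complete 2-sv tetrads
# and gains dead/one-spore tetrads relative to the control heterozygote.

eff = sporulation_efficiency(794, 6103)
print(f"\nsporulation efficiency example: {eff.rounded}% of 6103 cells")
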