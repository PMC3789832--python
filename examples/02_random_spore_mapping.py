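"""Random-spore map distances for the three chromosome III intervals.

When only two spores per tetrad survive (smt3-deletion strains), map
distances come from individual spores: cM = 100 * r/t with the binomial
standard error. This example reproduces the packaged published counts and
prints the per-strain chromosome III totals.
"""

from tetramap import SporeCounts, random_spore_distance
from tetramap.report import load_published_spore_counts, random_spore_map_report

# one interval by hand: 204 recombinants among 756 spores
est = random_spore_distance(SporeCounts(r=204, t=756), interval=("HIS4", "CEN3"))
print(f"HIS4-CEN3: {est.cM_rounded} cM (SE {est.SE_rounded}) from {est.n} spores")

# the full published panel from the packaged fixture
report = random_spore_map_report(
    load_published_spore_counts()[["strain", "interval", "r", "t"]]
)
totals = report[report["interval"] == "Total"]
print("\nchromosome III genetic length (sum of the three intervals):")
print(totals[["strain", "cM"]].round(0).to_string(index=False))
# SUMO-diminished strains (P_SCC1[SMT3] rows) total ~108-111 cM versus
# ~76-78 cM in controls: crossing over is elevated when SUMO is scarce.
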