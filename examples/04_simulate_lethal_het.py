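"""Simulating a lethal-heterozygote dissection and mapping from 2-sv spores.

The control_het scenario carries an unlinked haploid-lethal allele (the
smt3-deletion situation): most tetrads have exactly two viable spores, so
mapping must use the random-spore pool of 2-spore-viable tetrads. The
simulated dataset round-trips through the tetrad TSV dialect.
"""

import tempfile
from pathlib import Path

from tetramap import (
    build_study_scenario,
    read_tetrads,
    select_two_spore_viable,
    simulate_tetrads,
    viability_distribution,
    write_tetrads,
)
from tetramap.report import random_spore_map_report_from_tetrads

config = build_study_scenario("control_het", n_meioses=500, seed=11)
tetrads = simulate_tetrads(config)

dist = viability_distribution(tetrads)
print(f"viability classes (4..0 viable spores): "
      f"{[dist[k] for k in (4, 3, 2, 1, 0)]}")
# concentrated at 2-sv: the lethal allele kills two spores per tetrad, and
# background death plus rare gene conversion produce the tails.

pool = select_two_spore_viable(tetrads)
print(f"random-spore pool from 2-sv tetrads: {len(pool)} spores")
report = random_spore_map_report_from_tetrads(
    {"control_het sim": tetrads}, config.marker_map
)
print(report.round(1).to_string(index=False))
# the interval estimates track the scenario's recombination fractions; the
# Total row is the summed chromosome III genetic length.

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "sim.tsv"
    write_tetrads(path, tetrads, config.marker_map)
    again = read_tetrads(path, config.marker_map)
    print(f"\nTSV round trip: {len(again)} tetrads, identical = {again == tetrads}")
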