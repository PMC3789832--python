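# tetramap

Tetrad analysis, random-spore linkage mapping, crossover-interference
statistics, and a forward yeast-meiosis simulator.

## The problem

In budding yeast, crossover recombination is measured by dissecting tetrads
(the four spores of one meiosis) from a diploid heterozygous at linked
markers. When one parental chromosome carries a haploid-lethal allele — the
situation of a diploid heterozygous for a deletion of *SMT3*, the gene
encoding the SUMO precursor — two spores of every tetrad die, standard
tetrad mapping is impossible, and recombination must be estimated from the
surviving spores of two-spore-viable tetrads ("random-spore analysis").
`tetramap` implements that full analysis chain for such experiments, plus a
meiosis simulator that generates synthetic dissection data with the same
structure, so every estimator can be validated against a generative model
with known parameters.

It is written for geneticists analysing dissection tables: viability-class
statistics, map distances with standard errors, and interference tests, all
from plain TSV inputs or from simulated tetrads.

## Core statistics

For a two-locus interval, complete tetrads fall into parental ditype (PD),
tetratype (TT) and nonparental ditype (NPD) classes (`n = PD + TT + NPD`):

- **Random-spore distance** (spores, not tetrads): `cM = 100 r/t`, with
  binomial standard error `SE = 100 sqrt((r/t)(1 − r/t)/t)`, where `r` of
  `t` spores carry a recombinant two-locus combination. Only spores from
  tetrads with exactly two viable spores enter the pool in the lethal-het
  design.
- **Perkins tetrad distance**: `cM = 100 (TT/2 + 3 NPD)/n`, which corrects
  for double crossovers via the NPD class; its SE is a nonparametric
  bootstrap over tetrads.
- **Spore viability**: `100 (4 n₄ + 3 n₃ + 2 n₂ + n₁)/(4 N)` from the
  distribution of tetrads with 4…0 viable spores; class fractions are
  contrasted between strains with two-sided Fisher exact tests.
- **Crossover interference** (Papazian): the expected NPD fraction under no
  interference is `NPDᵉˣᵖ = ½(1 − f_TT − (1 − 3 f_TT/2)^{2/3})` from the
  observed tetratype fraction `f_TT`; the ratio `NPD_obs/NPD_exp < 1`
  indicates positive interference, tested with an exact binomial test
  (a Fisher 2×2 construction is available as an alternative mode).

The simulator places crossovers on a four-chromatid bivalent by a
chi-square/counting renewal process (interference parameter `m`; `m = 0` is
a Poisson process), picks non-sister chromatids uniformly (no chromatid
interference), and applies lethal-allele masking, gene conversion (3:1
segregation) and background spore death. See `docs/methods.md`.

## Worked example

```python
from tetramap import (SporeCounts, ViabilityDistribution,
                      compare_viability_classes, random_spore_distance,
                      spore_viability_percent)

control = ViabilityDistribution(counts={4: 1, 3: 4, 2: 280, 1: 25, 0: 3})
diminished = ViabilityDistribution(counts={4: 6, 3: 1, 2: 435, 1: 74, 0: 21})
print(spore_viability_percent(control).rounded)     # 48
print(spore_viability_percent(diminished).rounded)  # 45

table, p = compare_viability_classes(control, diminished, classes={2})
print(table.rows, round(p, 4))  # ((280, 33), (435, 102)) 0.0013

est = random_spore_distance(SporeCounts(r=204, t=756), ("HIS4", "CEN3"))
print(est.cM_rounded, est.SE_rounded)  # 27 1.6
```

The viability percentages are the printed integers of the dissection table;
`p = 0.0013` says the two-spore-viable fraction genuinely differs between
the control heterozygote and the SUMO-diminished strain; the last line is a
27 cM HIS4–CEN3 interval estimated from 756 spores with a 1.6 cM standard
error. The scripts in `examples/` extend this to the full strain panel,
Perkins mapping, interference testing and simulation round-trips.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes everything from scratch: the per-strain viability table and the
random-spore map table (with chromosome III totals) from the packaged count
fixtures, the two viability-contrast Fisher p-values, and a seeded
simulation round-trip for each built-in scenario, printing the reports it
computes and writing the results manifest to `--out`.
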