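# Methods

This note records the statistical model behind `tetramap`, the defaults and
why they were chosen, what the simulator does and does not emulate, and the
numerical choices a maintainer should know about.

## Data model

A dissection experiment is a list of tetrads; each tetrad has four spores
with a viability flag and an allele call (`P1`/`P2`) per marker locus.
Markers live on a `MarkerMap` with strictly increasing positions in cM, a
designated centromere locus, and optionally a named haploid-lethal locus.
If the lethal locus is not among the mapped loci it is treated as
genetically independent (on another chromosome) — the situation of an
*smt3* deletion relative to chromosome III test intervals.

### Filtering rules

- Interval classification (PD/TT/NPD) requires all four spores viable and
  genotyped, and 2:2 segregation at both loci. Tetrads failing this are
  `UNSCORABLE` for that interval only: a 3:1 gene-conversion event at one
  locus removes the tetrad from intervals touching that locus but leaves
  other intervals scorable. (How conversion-affected tetrads contributed to
  published whole-chromosome totals is not documented anywhere we know of;
  per-interval exclusion is the conservative choice and is logged.)
- Random-spore pools take the viable spores of exactly the two-spore-viable
  tetrads. In a lethal-het cross, 2-sv tetrads are the meioses in which
  both lethal-free spores survived; marker genotypes of those spores are
  unbiased for loci unlinked to the lethal, which is what licenses the
  design (and is verified by simulation in the test suite).
- A viable spore missing a call at a locus is dropped from random-spore
  counts for intervals touching that locus (logged); it never silently
  counts as parental.

## Estimators

- Random-spore: `cM = 100 r/t`, `SE = 100 sqrt(p(1−p)/t)`, `p = r/t`. Note
  this estimates the recombinant-gamete *fraction*; at distances ≳ 15 cM it
  sits below the physical map distance whenever interference is incomplete
  (Haldane shrinkage). That is a property of the assay, not a bug; the
  published tables report exactly this quantity.
- Perkins: `cM = 100 (TT/2 + 3 NPD)/n`. No analytic SE is attached because
  the published analyses delegated tetrad SEs to an external tool without
  printing a formula; instead the SE is a nonparametric bootstrap —
  resample `n` tetrads with replacement from the observed class proportions
  (`rng.multinomial`, B = 10,000 by default, seedable). Bootstrap SEs are
  therefore reproducible but not bit-comparable to any published SE.
- Viability percentages and sporulation efficiencies are computed at full
  precision and *reported* rounded half-up to integers, matching how such
  tables are printed; the raw value is always returned alongside.

## Fisher contrasts

`fisher_exact_two_sided` uses the probability-mass two-sided convention
(sum of hypergeometric probabilities of all tables with the observed
margins that are no more probable than the observed table) — the scipy/R
default. "Two-sided" has competing definitions; this one reproduces the
published contrast p-values (0.0013 for the 2-sv classes, 0.0004 for the
0+1-sv classes) from the tetrad-count tables. The 0+1-sv contrast is
computed over *tetrad* counts (28/313 vs 95/537), not spore counts: the
published phrasing ("among the total spores") is ambiguous, and only the
tetrad-unit table reproduces the printed p-value. Both interpretations can
be formed with `compare_viability_classes`; tetrad units are the default.

## Interference

The expected NPD fraction under independence is the Papazian function of
the observed tetratype fraction, `½(1 − f_TT − (1 − 3 f_TT/2)^{2/3})`,
defined on `0 ≤ f_TT ≤ 2/3`; values outside the domain raise (they cannot
arise without gross model failure), and a ~−1e−16 rounding residue near
`f_TT = 0` is clamped to zero. The significance of an NPD deficit is
assessed by an exact two-sided binomial test (minimum-likelihood
convention) of `NPD_obs` in `n` tetrads against the expected fraction. The
published analysis names "Fisher's Exact Test" for this comparison, but
observed-vs-expected proportions do not define a canonical 2×2 table; the
binomial null is exact and unambiguous, so it is the default, and a
`fisher2x2` mode (observed vs rounded-expected counts) is provided for
comparability. When the expected count is zero the ratio is reported as
NaN rather than raised so report tables render completely.

## The simulator

`simulate_tetrads` emulates one dissection experiment:

1. **Crossover placement** — a stationary counting (chi-square) renewal
   process: precursors are Poisson with mean `2(m+1)L/100` over a region of
   genetic length `L` cM; every `(m+1)`-th precursor (uniform random phase)
   matures into a crossover. `m = 0` is the no-interference Poisson model;
   `m ≈ 3–5` gives yeast-like positive interference. The intensity is
   calibrated so a region of length `d` cM receives on average `2d/100`
   crossovers per bivalent (`d/100` Morgans per chromatid, each crossover
   involving two of four chromatids), which makes interval lengths agree
   with the single-interval closed form
   `f_TT(d) = (2/3)(1 − e^{−3d/100})` and with Haldane's
   `r(d) = ½(1 − e^{−2d/100})` at `m = 0`.
2. **Exchange mechanics** — each crossover joins one chromatid from each
   homolog, chosen uniformly among the four non-sister pairs (no chromatid
   interference). Junctions bind to the original chromatid molecules and
   product strands are resolved by walking left to right, switching
   molecules at each junction involving the molecule currently traversed.
   This "follow the strand" resolution is required for map additivity: a
   naive swap of current segment contents reproduces single-interval
   closed forms but distorts interior intervals of a multi-marker map.
3. **Segregation** — products are grouped into the two meiosis-II pairs by
   centromere origin; reciprocity guarantees 2:2 segregation at every
   marker (a tested invariant when conversion is off).
4. **Lethal masking** — an unlinked lethal allele co-segregates with a
   uniformly chosen pole; both spores of that pole die. Gene conversion at
   the lethal locus (same per-locus rate) can flip one spore, producing
   the rare 3-viable or 1-viable lethal-het tetrads seen in real tables.
   Placing the lethal locus on the marker map links it instead (for stress
   tests).
5. **Gene conversion** — per locus per meiosis with probability
   `conversion_rate`, one chromatid's allele is overwritten (3:1 either
   direction).
6. **Background death** — each surviving spore dies independently with
   probability `background_death_rate`.

All randomness flows from a single numpy generator seeded by the config;
identical configs replay identical tetrad lists. Obligate crossing-over is
*not* enforced: zero-crossover bivalents occur at their renewal-process
frequency. This mildly fattens the PD class relative to real chromosome III
meioses but does not affect the estimators' validity.

### Scenario defaults

`build_study_scenario` encodes three strain archetypes. True inter-marker
distances are the corresponding published random-spore values; viability
knobs are calibrated from the published viability-class rows; the
interference parameter is a free choice because per-class tetrad counts
were never published for these strains:

| scenario | distances (cM) | lethal | death rate | m |
|---|---|---|---|---|
| `control_het` | 27, 19, 32 | yes | 0.05 | 3 |
| `sumo_diminished` | 34, 35, 40 | yes | 0.11 | 3 |
| `pch2_like` | 27, 27, 40 | no | 0.09 | 1 |

Death rates come from the 1-sv/0-sv tails of the matching viability rows
(e.g. `(25 + 2·3)/(2·313) ≈ 0.05` for the control heterozygote; a 91%
viability row implies ≈ 0.09, slightly above the 0.02–0.04 a 96% row would
give). The conversion rate default, 0.01 per locus per meiosis, is the
published non-mendelian event frequency (7 events across 4 loci in 175
tetrads). `pch2_like` uses `m = 1` to reflect the weaker interference
signal reported for *pch2* strains; this is a modeling choice, not a fit.

### What the simulator does not emulate

Crossover homeostasis, the recombination mechanism (DSB formation, ZMM
pathway), chromatid interference, obligate crossing-over, centromere
effects on conversion, and genotyping error. A green parameter-recovery
test therefore establishes that the estimators are consistent for the
stated generative model — not that real chromosome III meioses follow a
counting model with any particular `m`.

## Estimands and parameter-recovery checks

Because `100 r/t` estimates the recombinant fraction and Perkins corrects
only double crossovers, *no* generative model makes both estimators
unbiased for the nominal distance at `m = 0` and 27–32 cM intervals: the
random-spore expectation is Haldane-shrunk and the Perkins expectation at
32 cM is ≈ 29.5 cM (multiple-crossover bias). The recovery tests therefore
compare each estimator to its own model-implied expectation — Perkins
against an independent Poisson/Mather-chain enumeration, random-spore
against the Haldane fraction — within 2 SE, and additionally check
nominal-distance recovery at small distances where those biases are
negligible. Random-spore checks on unmasked data sample one spore per
tetrad, because the binomial SE presumes independent spores and the four
spores of one tetrad are correlated.

## Numerical choices

- Rounding for reports is half-up (away from zero), matching printed
  genetics tables; Python's banker's rounding is never used for display
  values.
- Fisher and binomial tests are delegated to scipy; the test suite carries
  independent enumeration oracles for both.
- Bootstrap SEs use `ddof = 1`; B = 10,000 keeps SE noise ≈ 1%.
- Tetrad TSV files are UTF-8 with a required header; free-text allele
  symbols map to `P1`/`P2` through `#phase locus P1allele P2allele`
  comment lines, abstracting drug-resistance/auxotrophy scores into binary
  alleles. Dead spores may carry `-` (missing) calls; simulated data keeps
  the true calls of dead spores, which classification ignores.

## Known limitations

- Tetrad-based (Perkins) SEs are bootstrap values and intentionally not
  comparable to any published tetrad SE.
- The interference test's `fisher2x2` mode rounds the expected count to an
  integer; it exists for comparability only and is cruder than the
  binomial default.
- Whole-chromosome "Total" values are sums of per-interval estimates; no
  SE is attached to a Total (the constituent estimates share spores and
  are not independent).
- The simulator's per-meiosis Python loop handles ~25k meioses/second;
  very large designs (≫10⁶ meioses) would want a vectorised rewrite.
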