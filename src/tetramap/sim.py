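"""Forward simulator of yeast meioses over a marked chromosome.

The simulator produces :class:`~tetramap.tetrads.Tetrad` records with the
structure tetrad-dissection data has in a cross heterozygous at several
linked markers:

* A bivalent of four chromatids (two sisters per homolog).  Crossovers are
  placed along the marked region by a chi-square/counting renewal process:
  precursor events form a Poisson process and every (m+1)-th precursor
  (random phase) matures into a crossover, so ``m = 0`` gives no interference
  (Poisson crossovers) and larger ``m`` gives stronger positive interference.
* Each crossover involves one chromatid from each homolog, chosen uniformly
  among the four non-sister pairs (no chromatid interference -- the standard
  assumption behind the Perkins formula), and reciprocally exchanges the
  segments distal to the exchange point.
* Intensity calibration: a region of genetic length d cM receives on average
  ``2 d/100`` crossovers per bivalent (d/100 Morgans per chromatid; each
  crossover involves two of the four chromatids), which makes the realised
  map distance of an interval equal its nominal length.
* A heterozygous haploid-lethal locus (the *smt3* deletion situation) kills
  the two spores that inherit it.  By default it segregates independently of
  the marked chromosome: the two spores derived from one pole of meiosis I
  die.  Placing the lethal locus on the marker map instead links it.
* Gene conversion: with a small per-locus, per-meiosis probability one
  chromatid's allele is overwritten, giving 3:1 segregation at that marker
  (which removes the tetrad from interval classification at intervals
  touching it, and can rescue a third spore when it hits the lethal locus).
* Background spore death: each otherwise-viable spore dies independently
  with a small probability, reproducing the 3-sv/1-sv tails of real
  dissection tables.

All randomness flows from one ``numpy`` generator seeded by
``SimulationConfig.seed``, so a config replays exactly.

Obligate crossing-over is *not* enforced: zero-crossover bivalents occur at
their Poisson/counting-process frequency.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Dict, List, Tuple

import math

import numpy as np

from .tetrads import P1, P2, MarkerMap, Spore, Tetrad

__all__ = [
    "SimulationConfig",
    "place_crossovers",
    "simulate_tetrads",
    "expected_tetratype_fraction",
    "build_study_scenario",
    "SCENARIO_NAMES",
]

_PAIRS: Tuple[Tuple[int, int], ...] = ((0, 2), (0, 3), (1, 2), (1, 3))


@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of one simulated dissection experiment."""

    marker_map: MarkerMap
    n_meioses: int
    interference_m: int = 0
    lethal_locus_present: bool = False
    background_death_rate: float = 0.0
    conversion_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_meioses <= 0:
            raise ValueError("n_meioses must be positive")
        if self.interference_m < 0 or int(self.interference_m) != self.interference_m:
            raise ValueError("interference_m must be a non-negative integer")
        for name in ("background_death_rate", "conversion_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        if self.lethal_locus_present and self.marker_map.lethal_locus is None:
            raise ValueError(
                "lethal_locus_present requires marker_map.lethal_locus to be named"
            )


def place_crossovers(
    total_length_cM: float,
    m: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Crossover positions (cM) on one bivalent for a region of the given
    genetic length, under the counting model with interference parameter m.

    Precursors are a Poisson process with mean ``2 (m+1) L/100`` events over
    the region; every (m+1)-th precursor, at a uniformly random phase offset,
    becomes a crossover, leaving on average ``2 L/100`` crossovers per
    bivalent regardless of m.  ``m = 0`` keeps every precursor (no
    interference).
    """
    if total_length_cM < 0:
        raise ValueError("length must be non-negative")
    if total_length_cM == 0:
        return np.empty(0)
    k = rng.poisson(2.0 * (m + 1) * total_length_cM / 100.0)
    if k == 0:
        return np.empty(0)
    positions = np.sort(rng.random(k) * total_length_cM)
    if m == 0:
        return positions
    phase = int(rng.integers(0, m + 1))
    return positions[phase :: m + 1]


def expected_tetratype_fraction(d_cM: float) -> float:
    """Closed-form tetratype fraction for a single interval of length d under
    the no-interference (m = 0) model: fTT(d) = (2/3)(1 - e^(-3d/100)).

    Used to validate the simulator, not to analyse data.
    """
    if d_cM < 0:
        raise ValueError("distance must be non-negative")
    return (2.0 / 3.0) * (1.0 - math.exp(-3.0 * d_cM / 100.0))


def simulate_tetrads(config: SimulationConfig) -> List[Tetrad]:
    """Simulate ``config.n_meioses`` meioses and return their tetrads.

    Spores are ordered by meiosis-II pair: spores 1-2 come from one pole of
    the first division, spores 3-4 from the other.  Dead spores retain their
    (in reality unobservable) allele calls, which downstream classification
    ignores.
    """
    config.validate()
    mm = config.marker_map
    names = mm.locus_names
    positions = list(mm.positions)
    n_loci = len(names)
    full_mask = (1 << n_loci) - 1
    origin = positions[0]
    length = positions[-1] - positions[0]
    cen_idx = names.index(mm.centromere_locus)
    lethal_linked = config.lethal_locus_present and mm.lethal_is_linked
    lethal_idx = names.index(mm.lethal_locus) if lethal_linked else -1

    rng = np.random.default_rng(config.seed)
    n = config.n_meioses
    # batched per-meiosis draws (order of consumption is part of the replay
    # contract but has no statistical meaning)
    death_draws = rng.random((n, 4))
    conv_events = rng.random((n, n_loci)) < config.conversion_rate
    conv_targets = rng.integers(0, 4, size=(n, n_loci))
    lethal_sides = rng.integers(0, 2, size=n)
    lethal_conv = rng.random(n) < config.conversion_rate
    lethal_conv_spore = rng.integers(0, 4, size=n)

    tetrads: List[Tetrad] = []
    for i in range(n):
        # Crossover junctions join the four original chromatid molecules
        # (0,1 = sisters of homolog 1; 2,3 = homolog 2); product strands are
        # resolved by walking left to right and switching molecules at every
        # junction involving the molecule currently being traversed.  Bit j
        # of a product mask is 1 when the P2 allele is carried at locus j.
        cur = [0, 1, 2, 3]  # product index -> molecule currently traversed
        chromatids = [0, 0, 0, 0]
        next_locus = 0

        def _advance(upto: int) -> None:
            nonlocal next_locus
            while next_locus < upto:
                bit = 1 << next_locus
                for q in range(4):
                    if cur[q] >= 2:
                        chromatids[q] |= bit
                next_locus += 1

        for pos in place_crossovers(length, config.interference_m, rng):
            a, b = _PAIRS[int(rng.integers(0, 4))]
            _advance(bisect_right(positions, origin + pos))
            ia, ib = cur.index(a), cur.index(b)
            cur[ia], cur[ib] = b, a
        _advance(n_loci)

        # meiosis I segregates by centromere origin (pre-conversion)
        cen_bit = 1 << cen_idx
        pole1 = [c for c in chromatids if not c & cen_bit]
        pole2 = [c for c in chromatids if c & cen_bit]
        ordered = pole1 + pole2

        for j in range(n_loci):
            if conv_events[i, j]:
                ordered[conv_targets[i, j]] ^= 1 << j

        if config.lethal_locus_present:
            if lethal_linked:
                carries_lethal = [bool(c & (1 << lethal_idx)) for c in ordered]
            else:
                side = lethal_sides[i]
                carries_lethal = [s // 2 == side for s in range(4)]
                if lethal_conv[i]:
                    s = lethal_conv_spore[i]
                    carries_lethal[s] = not carries_lethal[s]
        else:
            carries_lethal = [False] * 4

        spores = tuple(
            Spore(
                spore_id=s + 1,
                viable=(
                    not carries_lethal[s]
                    and death_draws[i, s] >= config.background_death_rate
                ),
                alleles={
                    name: (P2 if ordered[s] & (1 << j) else P1)
                    for j, name in enumerate(names)
                },
            )
            for s in range(4)
        )
        tetrads.append(Tetrad(tetrad_id=f"t{i + 1}", spores=spores))
    return tetrads


# Scenario constants emulate the dissection tables of the SUMO-diminished
# chromosome III cross: true distances are the published random-spore
# estimates for the corresponding strain, the lethal knob encodes smt3
# heterozygosity, and death/conversion rates are calibrated to the published
# viability-class distributions (see docs/methods.md).
_SCENARIOS: Dict[str, dict] = {
    # smt3-deletion heterozygote, SMT3 expression normal (control)
    "control_het": dict(
        distances=(27.0, 19.0, 32.0),
        lethal=True,
        death=0.05,
        m=3,
    ),
    # smt3-deletion heterozygote with mitotic-promoter SMT3 (SUMO-diminished)
    "sumo_diminished": dict(
        distances=(34.0, 35.0, 40.0),
        lethal=True,
        death=0.11,
        m=3,
    ),
    # pch2 null, no lethal allele; interference weakened
    "pch2_like": dict(
        distances=(27.0, 27.0, 40.0),
        lethal=False,
        death=0.09,
        m=1,
    ),
}
SCENARIO_NAMES: Tuple[str, ...] = tuple(_SCENARIOS)
_CONVERSION_RATE = 0.01  # per locus per meiosis, from published 3:1 frequencies


def chromosome_iii_map(
    distances: Tuple[float, float, float] = (27.0, 19.0, 32.0),
    lethal: bool = True,
) -> MarkerMap:
    """The four-marker chromosome III map (HIS4, CEN3 marker, MAT, RAD18
    marker) with the given inter-marker distances; the lethal SMT3 locus, if
    present, segregates independently."""
    d1, d2, d3 = distances
    return MarkerMap(
        chromosome_label="III",
        loci=(
            ("HIS4", 0.0),
            ("CEN3", d1),
            ("MAT", d1 + d2),
            ("RAD18", d1 + d2 + d3),
        ),
        centromere_locus="CEN3",
        lethal_locus="SMT3" if lethal else None,
    )


def build_study_scenario(
    name: str,
    n_meioses: int = 300,
    seed: int = 0,
) -> SimulationConfig:
    """Ready-made configs emulating the study strains.

    ``control_het``: smt3Δ/+ control, distances (27, 19, 32) cM.
    ``sumo_diminished``: SUMO-diminished, distances (34, 35, 40) cM.
    ``pch2_like``: pch2 null without the lethal allele, distances (27, 27, 40).
    """
    try:
        params = _SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}"
        ) from None
    return SimulationConfig(
        marker_map=chromosome_iii_map(params["distances"], lethal=params["lethal"]),
        n_meioses=n_meioses,
        interference_m=params["m"],
        lethal_locus_present=params["lethal"],
        background_death_rate=params["death"],
        conversion_rate=_CONVERSION_RATE,
        seed=seed,
    )
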