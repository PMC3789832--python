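"""Core domain objects for yeast tetrad analysis.

A tetrad is the set of four haploid spores produced by one meiosis of a
diploid, recovered as a unit by dissection.  For any pair of heterozygous
markers a fully viable, normally segregating tetrad falls into one of three
classes -- parental ditype (PD), tetratype (TT) or nonparental ditype (NPD) --
which carry the information used for linkage mapping and crossover
interference analysis.

Alleles are abstracted to the two parental symbols ``P1`` and ``P2``: parent 1
contributes ``P1`` at every locus, parent 2 contributes ``P2``.  Free-text
phenotype scores (drug resistance, auxotrophy) are mapped onto these symbols
at file-reading time.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Tuple

__all__ = [
    "P1",
    "P2",
    "MarkerMap",
    "Spore",
    "Tetrad",
    "TetradClass",
    "TetradClassCounts",
    "ViabilityDistribution",
    "classify_interval",
    "count_interval_classes",
    "viability_distribution",
    "select_two_spore_viable",
]

P1 = "P1"
P2 = "P2"
_ALLELES = (P1, P2)


class TetradClass(str, Enum):
    """Two-locus configuration of a complete tetrad."""

    PD = "PD"
    TT = "TT"
    NPD = "NPD"
    UNSCORABLE = "UNSCORABLE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class MarkerMap:
    """Ordered heterozygous marker loci on one chromosome.

    Parameters
    ----------
    chromosome_label
        Display name of the chromosome (e.g. ``"III"``).
    loci
        Ordered ``(name, position_cM)`` pairs; positions strictly increasing.
    centromere_locus
        Name of the locus marking the centromere (must be in ``loci``).
    lethal_locus
        Optional name of a heterozygous haploid-lethal locus.  If the name is
        not among ``loci`` the locus is modeled as genetically independent
        (on another chromosome), the situation of an *smt3* deletion relative
        to chromosome III markers.
    """

    chromosome_label: str
    loci: Tuple[Tuple[str, float], ...]
    centromere_locus: str
    lethal_locus: Optional[str] = None

    def __init__(
        self,
        chromosome_label: str,
        loci: Iterable[Tuple[str, float]],
        centromere_locus: str,
        lethal_locus: Optional[str] = None,
    ) -> None:
        loci = tuple((str(n), float(p)) for n, p in loci)
        if not loci:
            raise ValueError("marker map needs at least one locus")
        names = [n for n, _ in loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names in marker map")
        positions = [p for _, p in loci]
        if any(p < 0 for p in positions):
            raise ValueError("locus positions must be non-negative")
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("locus positions must be strictly increasing")
        if centromere_locus not in names:
            raise ValueError(f"centromere locus {centromere_locus!r} not in map")
        object.__setattr__(self, "chromosome_label", chromosome_label)
        object.__setattr__(self, "loci", loci)
        object.__setattr__(self, "centromere_locus", centromere_locus)
        object.__setattr__(self, "lethal_locus", lethal_locus)

    @property
    def locus_names(self) -> Tuple[str, ...]:
        return tuple(n for n, _ in self.loci)

    @property
    def positions(self) -> Tuple[float, ...]:
        return tuple(p for _, p in self.loci)

    def position_of(self, locus: str) -> float:
        for n, p in self.loci:
            if n == locus:
                return p
        raise KeyError(locus)

    @property
    def lethal_is_linked(self) -> bool:
        """True when the lethal locus sits on this marker map."""
        return self.lethal_locus is not None and self.lethal_locus in self.locus_names

    def interval_length(self, locusA: str, locusB: str) -> float:
        return abs(self.position_of(locusB) - self.position_of(locusA))


@dataclass(frozen=True, slots=True)
class Spore:
    """One haploid spore: viability flag plus allele calls per locus.

    ``alleles`` maps locus name to ``"P1"``/``"P2"``; a missing call is
    ``None`` (only meaningful for real data -- dead spores, failed scores).
    """

    spore_id: int
    viable: bool
    alleles: Mapping[str, Optional[str]]

    def __post_init__(self) -> None:
        if self.spore_id not in (1, 2, 3, 4):
            raise ValueError(f"spore_id must be 1-4, got {self.spore_id}")
        for locus, allele in self.alleles.items():
            if allele is not None and allele not in _ALLELES:
                raise ValueError(
                    f"allele {allele!r} at {locus!r} not in {{P1, P2}}"
                )


@dataclass(frozen=True, slots=True)
class Tetrad:
    """Four spores from one meiosis."""

    tetrad_id: str
    spores: Tuple[Spore, Spore, Spore, Spore]

    def __post_init__(self) -> None:
        if len(self.spores) != 4:
            raise ValueError(
                f"tetrad {self.tetrad_id!r} has {len(self.spores)} spores, need 4"
            )

    @property
    def n_viable(self) -> int:
        return sum(s.viable for s in self.spores)

    @property
    def viable_spores(self) -> Tuple[Spore, ...]:
        return tuple(s for s in self.spores if s.viable)


@dataclass(frozen=True)
class TetradClassCounts:
    """PD/TT/NPD counts for one marker interval."""

    interval: Tuple[str, str]
    PD: int
    TT: int
    NPD: int

    def __post_init__(self) -> None:
        if min(self.PD, self.TT, self.NPD) < 0:
            raise ValueError("tetrad class counts must be non-negative")

    @property
    def n(self) -> int:
        return self.PD + self.TT + self.NPD

    @property
    def f_tt(self) -> float:
        """Observed tetratype fraction fTT = TT/n."""
        if self.n == 0:
            raise ZeroDivisionError("no classified tetrads")
        return self.TT / self.n


@dataclass(frozen=True)
class ViabilityDistribution:
    """Counts of tetrads by number of viable spores (4-sv ... 0-sv)."""

    counts: Mapping[int, int]
    total_tetrads: int = field(default=-1)

    def __post_init__(self) -> None:
        counts = {k: int(self.counts.get(k, 0)) for k in range(5)}
        if set(self.counts) - set(range(5)):
            raise ValueError("viable-spore counts must be keyed by 0..4")
        if any(v < 0 for v in counts.values()):
            raise ValueError("tetrad counts must be non-negative")
        total = sum(counts.values())
        if self.total_tetrads == -1:
            object.__setattr__(self, "total_tetrads", total)
        elif self.total_tetrads != total:
            raise ValueError(
                f"counts sum to {total}, not total_tetrads={self.total_tetrads}"
            )
        object.__setattr__(self, "counts", counts)

    def __getitem__(self, k: int) -> int:
        return self.counts[k]


def _segregates_2_2(tetrad: Tetrad, locus: str) -> bool:
    calls = Counter(s.alleles[locus] for s in tetrad.spores)
    return calls.get(P1, 0) == 2 and calls.get(P2, 0) == 2


def classify_interval(
    tetrad: Tetrad,
    locusA: str,
    locusB: str,
    parental_phase: Tuple[str, str] = (P1, P1),
) -> TetradClass:
    """Classify a tetrad as PD, TT or NPD for the interval ``locusA-locusB``.

    ``parental_phase`` gives the two-locus allele combination carried by one
    parent; the other parental combination is its complement.  A tetrad is
    scorable only when all four spores are viable and genotyped at both loci
    and each locus segregates 2:2 (a 3:1 gene-conversion event at either locus
    makes the interval unscorable for this tetrad, without affecting other
    intervals).

    Returns :class:`TetradClass`; ``UNSCORABLE`` is a value, never an error.
    """
    if locusA == locusB:
        raise ValueError("interval endpoints must be distinct loci")
    for locus, allele in zip((locusA, locusB), parental_phase):
        if allele not in _ALLELES:
            raise ValueError(f"phase allele {allele!r} not in {{P1, P2}}")
    for spore in tetrad.spores:
        if not spore.viable:
            return TetradClass.UNSCORABLE
        if spore.alleles.get(locusA) is None or spore.alleles.get(locusB) is None:
            return TetradClass.UNSCORABLE
    if not (_segregates_2_2(tetrad, locusA) and _segregates_2_2(tetrad, locusB)):
        return TetradClass.UNSCORABLE

    parental = {parental_phase, _complement(parental_phase)}
    n_parental = sum(
        (s.alleles[locusA], s.alleles[locusB]) in parental for s in tetrad.spores
    )
    # with 2:2 segregation at both loci only 4, 2 or 0 parental spores can occur
    if n_parental == 4:
        return TetradClass.PD
    if n_parental == 0:
        return TetradClass.NPD
    return TetradClass.TT


def _complement(phase: Tuple[str, str]) -> Tuple[str, str]:
    flip = {P1: P2, P2: P1}
    return (flip[phase[0]], flip[phase[1]])


def count_interval_classes(
    tetrads: Iterable[Tetrad],
    locusA: str,
    locusB: str,
    parental_phase: Tuple[str, str] = (P1, P1),
) -> TetradClassCounts:
    """Tally PD/TT/NPD over tetrads, silently dropping UNSCORABLE ones."""
    tally = Counter(
        classify_interval(t, locusA, locusB, parental_phase) for t in tetrads
    )
    return TetradClassCounts(
        interval=(locusA, locusB),
        PD=tally.get(TetradClass.PD, 0),
        TT=tally.get(TetradClass.TT, 0),
        NPD=tally.get(TetradClass.NPD, 0),
    )


def viability_distribution(tetrads: Iterable[Tetrad]) -> ViabilityDistribution:
    """Distribution of tetrads over viable-spore count classes 0..4."""
    tally = Counter(t.n_viable for t in tetrads)
    return ViabilityDistribution(counts={k: tally.get(k, 0) for k in range(5)})


def select_two_spore_viable(tetrads: Iterable[Tetrad]) -> list[Spore]:
    """Viable spores of exactly the 2-spore-viable tetrads.

    This is the random-spore pool used when a heterozygous haploid-lethal
    allele (e.g. an *smt3* deletion) caps viability at two spores per tetrad:
    restricting to 2-sv tetrads selects meioses where both lethal-free spores
    survived, leaving marker genotypes unbiased for loci unlinked to the
    lethal.
    """
    pool: list[Spore] = []
    for tetrad in tetrads:
        if tetrad.n_viable == 2:
            pool.extend(tetrad.viable_spores)
    return pool
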