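"""Sporulation and spore-viability statistics.

Spore viability of a dissected strain is the fraction of all dissected spores
that formed colonies, computed from the distribution of tetrads over
viable-spore classes:

    viability = (4*n4 + 3*n3 + 2*n2 + 1*n1) / (4 * total tetrads)

Strains heterozygous for a haploid-lethal allele (e.g. *smt3*Δ/+) are capped
at 50% viability because two spores of every tetrad inherit the lethal allele.
Contrasts between strains' viability-class fractions use Fisher's exact test
on 2x2 tetrad-count tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Tuple

from scipy import stats

from .tetrads import ViabilityDistribution

__all__ = [
    "FisherTable",
    "SporeViability",
    "spore_viability_percent",
    "sporulation_efficiency",
    "fisher_exact_two_sided",
    "compare_viability_classes",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (the convention of
    printed genetics tables, unlike Python's banker's rounding)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class FisherTable:
    """2x2 contingency table, rows = groups, columns = in/out of class."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")

    @property
    def rows(self) -> Tuple[Tuple[int, int], Tuple[int, int]]:
        return ((self.a, self.b), (self.c, self.d))


class SporeViability(NamedTuple):
    """Raw percentage plus the integer value used in printed tables."""

    raw: float
    rounded: int


def spore_viability_percent(dist: ViabilityDistribution) -> SporeViability:
    """Overall spore viability (%) from a viability-class distribution."""
    if dist.total_tetrads == 0:
        raise ValueError("spore viability undefined for zero tetrads")
    viable_spores = sum(k * dist[k] for k in range(5))
    raw = 100.0 * viable_spores / (4 * dist.total_tetrads)
    return SporeViability(raw=raw, rounded=round_half_up(raw))


def sporulation_efficiency(sporulated: int, total: int) -> SporeViability:
    """Percentage of cells that formed asci, as printed: integer % with raw."""
    if total <= 0:
        raise ValueError("sporulation efficiency undefined for zero cells")
    if not 0 <= sporulated <= total:
        raise ValueError("sporulated count must lie in [0, total]")
    raw = 100.0 * sporulated / total
    return SporeViability(raw=raw, rounded=round_half_up(raw))


def fisher_exact_two_sided(table: FisherTable) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Uses the probability-mass definition (sum of hypergeometric probabilities
    of all tables with the same margins that are no more probable than the
    observed one), the convention of the mainstream statistical ecosystems.
    """
    return float(stats.fisher_exact(table.rows, alternative="two-sided")[1])


def compare_viability_classes(
    dist1: ViabilityDistribution,
    dist2: ViabilityDistribution,
    classes: Iterable[int],
) -> Tuple[FisherTable, float]:
    """Fisher contrast of the tetrad fraction falling in ``classes``.

    Builds the 2x2 table (in-class vs out-of-class tetrad counts for each
    strain) and returns it with the two-sided exact p-value.  For example the
    2-spore-viable contrast uses ``classes={2}``; the combined dead/one-spore
    contrast uses ``classes={0, 1}``.
    """
    classes = set(classes)
    if not classes:
        raise ValueError("empty viability class set")
    if not classes <= set(range(5)):
        raise ValueError("viability classes must be within 0..4")
    if dist1.total_tetrads == 0 or dist2.total_tetrads == 0:
        raise ValueError("both distributions must contain tetrads")
    in1 = sum(dist1[k] for k in classes)
    in2 = sum(dist2[k] for k in classes)
    table = FisherTable(
        a=in1,
        b=dist1.total_tetrads - in1,
        c=in2,
        d=dist2.total_tetrads - in2,
    )
    return table, fisher_exact_two_sided(table)
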