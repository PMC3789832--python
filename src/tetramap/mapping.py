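"""Genetic map distances and crossover-interference statistics.

Two estimators of map distance are provided:

* **Random-spore**: cM = 100 * r/t over individual viable spores, with the
  binomial standard error 100 * sqrt((r/t)(1 - r/t)/t).  This is the only
  estimator available when a heterozygous haploid-lethal allele restricts
  dissections to 2-spore-viable tetrads.
* **Perkins (tetrad)**: cM = 100 * (TT/2 + 3*NPD)/n from complete tetrads,
  which corrects for double crossovers via the NPD class.  No closed-form
  standard error is attached; the SE is a nonparametric bootstrap over
  tetrads.

Crossover interference is quantified by comparing observed nonparental
ditypes with the count expected under independence, derived from the
observed tetratype fraction fTT (Papazian):

    NPD_exp fraction = 1/2 * (1 - fTT - (1 - 3*fTT/2)^(2/3))

A ratio NPD_obs/NPD_exp below one indicates positive interference.  The
significance of the deficit is assessed by an exact binomial test of NPD_obs
against the expected NPD fraction (default), or by a Fisher 2x2 construction
against the rounded expected count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .tetrads import P1, P2, Spore, TetradClassCounts
from .viability import FisherTable, fisher_exact_two_sided, round_half_up

__all__ = [
    "SporeCounts",
    "IntervalEstimate",
    "InterferenceResult",
    "spore_pool_counts",
    "random_spore_distance",
    "perkins_distance",
    "papazian_expected_npd_fraction",
    "interference_test",
    "map_table",
]


@dataclass(frozen=True)
class SporeCounts:
    """Recombinant (r) and total (t) colony counts for one interval."""

    r: int
    t: int

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError("total spore count t must be positive")
        if not 0 <= self.r <= self.t:
            raise ValueError("recombinant count r must satisfy 0 <= r <= t")


@dataclass(frozen=True)
class IntervalEstimate:
    """A map-distance estimate for one interval.

    ``cM`` and ``SE`` carry full precision; printed tables round cM to the
    nearest integer and SE to one decimal.
    """

    interval: Tuple[str, str]
    cM: float
    SE: float
    n: int
    method: str  # "random_spore" | "perkins"

    @property
    def cM_rounded(self) -> int:
        return round_half_up(self.cM)

    @property
    def SE_rounded(self) -> float:
        return round_half_up(self.SE * 10) / 10


@dataclass(frozen=True)
class InterferenceResult:
    """Observed-vs-expected NPD comparison for one interval."""

    interval: Tuple[str, str]
    f_tt: float
    npd_obs: int
    npd_exp: float  # expected count, n * Papazian fraction
    ratio: float  # NPD_obs / NPD_exp; NaN when npd_exp == 0
    p_two_sided: float
    n: int
    mode: str  # "binomial" | "fisher2x2"


def spore_pool_counts(
    spores: Iterable[Spore],
    locusA: str,
    locusB: str,
    parental_phase: Tuple[str, str] = (P1, P1),
) -> SporeCounts:
    """Recombinant/total counts for an interval over a random-spore pool.

    A spore is recombinant when its two-locus combination differs from both
    parental combinations.  Spores missing a call at either locus are
    excluded from this interval (conservative handling of partial scores);
    the exclusion count is visible as ``t`` falling short of the pool size.
    """
    flip = {P1: P2, P2: P1}
    parental = {tuple(parental_phase), (flip[parental_phase[0]], flip[parental_phase[1]])}
    r = t = 0
    for spore in spores:
        a, b = spore.alleles.get(locusA), spore.alleles.get(locusB)
        if a is None or b is None:
            continue
        t += 1
        if (a, b) not in parental:
            r += 1
    return SporeCounts(r=r, t=t)


def random_spore_distance(
    counts: SporeCounts,
    interval: Tuple[str, str] = ("A", "B"),
) -> IntervalEstimate:
    """Map distance from a random-spore pool: 100*r/t with binomial SE."""
    p = counts.r / counts.t
    return IntervalEstimate(
        interval=interval,
        cM=100.0 * p,
        SE=100.0 * math.sqrt(p * (1.0 - p) / counts.t),
        n=counts.t,
        method="random_spore",
    )


def perkins_distance(
    counts: TetradClassCounts,
    n_boot: int = 10_000,
    rng: Optional[Union[int, np.random.Generator]] = None,
) -> IntervalEstimate:
    """Perkins map distance 100*(TT/2 + 3*NPD)/n with bootstrap SE.

    The SE resamples n tetrads with replacement from the observed class
    proportions (``n_boot`` replicates, seedable through ``rng``), i.e. a
    multinomial parametric-free bootstrap over tetrads.
    """
    n = counts.n
    if n == 0:
        raise ValueError("Perkins distance undefined with no classified tetrads")
    cm = 100.0 * (counts.TT / 2.0 + 3.0 * counts.NPD) / n
    generator = np.random.default_rng(rng)
    resampled = generator.multinomial(
        n, [counts.PD / n, counts.TT / n, counts.NPD / n], size=n_boot
    )
    boot_cm = 100.0 * (resampled[:, 1] / 2.0 + 3.0 * resampled[:, 2]) / n
    return IntervalEstimate(
        interval=counts.interval,
        cM=cm,
        SE=float(np.std(boot_cm, ddof=1)),
        n=n,
        method="perkins",
    )


def papazian_expected_npd_fraction(f_tt: float) -> float:
    """Expected NPD fraction from the tetratype fraction, assuming no
    interference: 1/2 * (1 - fTT - (1 - 3*fTT/2)^(2/3)).

    Defined on 0 <= fTT <= 2/3 (fTT above 2/3 would put a negative base under
    the fractional power and cannot arise without negative interference so
    extreme that the model's assumptions fail).
    """
    if not 0.0 <= f_tt <= 2.0 / 3.0:
        raise ValueError(f"fTT must lie in [0, 2/3], got {f_tt}")
    # clamp: the expression is mathematically >= 0 on the domain but can
    # round to ~-1e-16 near fTT = 0
    return max(0.0, 0.5 * (1.0 - f_tt - (1.0 - 1.5 * f_tt) ** (2.0 / 3.0)))


def interference_test(
    counts: TetradClassCounts,
    mode: str = "binomial",
) -> InterferenceResult:
    """Test the observed NPD count against the Papazian expectation.

    ``mode="binomial"`` (default): exact two-sided binomial test of NPD_obs
    successes in n tetrads against success probability equal to the expected
    NPD fraction (minimum-likelihood two-sided convention).

    ``mode="fisher2x2"``: Fisher exact test of (NPD_obs, n - NPD_obs) against
    (round(NPD_exp), n - round(NPD_exp)) -- a cruder construction matching
    how "Fisher's exact test" is sometimes applied to observed-vs-expected
    proportions; provided for comparability, the binomial mode is preferred.

    When the expected count is zero the ratio is reported as NaN (not raised)
    so that report tables render completely; p is 1 when no NPDs were
    observed either, else 0.
    """
    n = counts.n
    if n == 0:
        raise ValueError("interference test undefined with no tetrads")
    f_tt = counts.f_tt
    frac_exp = papazian_expected_npd_fraction(f_tt)
    npd_exp = n * frac_exp
    ratio = counts.NPD / npd_exp if npd_exp > 0 else math.nan

    if mode == "binomial":
        if frac_exp == 0.0:
            p = 1.0 if counts.NPD == 0 else 0.0
        else:
            p = float(stats.binomtest(counts.NPD, n, frac_exp).pvalue)
    elif mode == "fisher2x2":
        expected_count = round_half_up(npd_exp)
        table = FisherTable(
            a=counts.NPD, b=n - counts.NPD, c=expected_count, d=n - expected_count
        )
        p = fisher_exact_two_sided(table)
    else:
        raise ValueError(f"unknown interference test mode {mode!r}")

    return InterferenceResult(
        interval=counts.interval,
        f_tt=f_tt,
        npd_obs=counts.NPD,
        npd_exp=npd_exp,
        ratio=ratio,
        p_two_sided=p,
        n=n,
        mode=mode,
    )


def map_table(
    per_strain: Mapping[str, Sequence[IntervalEstimate]],
    total_label: str = "Total",
) -> pd.DataFrame:
    """Assemble per-strain interval estimates into a long-form report table.

    One row per strain and interval with columns ``strain``, ``interval``,
    ``method``, ``cM``, ``SE``, ``n``, plus one ``Total`` row per strain whose
    cM is the sum of that strain's interval estimates (the chromosome-wide
    genetic length).
    """
    records: List[dict] = []
    for strain, estimates in per_strain.items():
        for est in estimates:
            records.append(
                {
                    "strain": strain,
                    "interval": "-".join(est.interval),
                    "method": est.method,
                    "cM": est.cM,
                    "SE": est.SE,
                    "n": est.n,
                }
            )
        records.append(
            {
                "strain": strain,
                "interval": total_label,
                "method": estimates[0].method if estimates else "",
                "cM": sum(e.cM for e in estimates),
                "SE": math.nan,
                "n": min((e.n for e in estimates), default=0),
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["strain", "interval", "method", "cM", "SE", "n"]
    )
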