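"""Shared fixtures and independent statistical oracles.

The oracles here are deliberately naive (enumeration, closed forms) and
independent of the package's implementation paths; tests freeze expected
values computed with them.
"""

from __future__ import annotations

import math
from typing import Sequence, Tuple

import pytest

from tetramap import MarkerMap, P1, P2, Spore, Tetrad


def make_tetrad(
    genotypes: Sequence[str],
    loci: Sequence[str] = ("A", "B"),
    viable: Sequence[bool] = (True, True, True, True),
    tid: str = "t1",
) -> Tetrad:
    """Build a tetrad from compact genotype strings.

    Each genotype string has one character per locus: an uppercase letter
    denotes the P1 allele, lowercase the P2 allele, ``.`` a missing call.
    ``make_tetrad(["AB", "AB", "ab", "ab"])`` is a parental ditype.
    """
    spores = []
    for i, (geno, viab) in enumerate(zip(genotypes, viable), start=1):
        alleles = {}
        for locus, ch in zip(loci, geno):
            alleles[locus] = None if ch == "." else (P1 if ch.isupper() else P2)
        spores.append(Spore(spore_id=i, viable=viab, alleles=alleles))
    return Tetrad(tetrad_id=tid, spores=tuple(spores))


@pytest.fixture
def two_locus_map() -> MarkerMap:
    return MarkerMap("X", [("A", 0.0), ("B", 20.0)], centromere_locus="A")


# ---------------------------------------------------------------------------
# independent oracles


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Brute-force two-sided Fisher p: enumerate all tables with the observed
    margins and sum the hypergeometric probabilities of those no more
    probable than the observed table."""
    r1, c1, n = a + b, a + c, a + b + c + d

    def prob(k: int) -> float:
        return (
            math.comb(c1, k)
            * math.comb(n - c1, r1 - k)
            / math.comb(n, r1)
        )

    p_obs = prob(a)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


def binom_two_sided_oracle(k_obs: int, n: int, p: float) -> float:
    """Brute-force two-sided exact binomial p (minimum-likelihood method):
    sum of binomial pmf over outcomes no more probable than the observed."""
    def pmf(k: int) -> float:
        return math.comb(n, k) * p**k * (1 - p) ** (n - k)

    p_obs = pmf(k_obs)
    total = sum(pmf(k) for k in range(n + 1) if pmf(k) <= p_obs * (1 + 1e-9))
    return min(total, 1.0)


def mather_class_fractions(x: float, kmax: int = 120) -> Tuple[float, float, float]:
    """Expected (PD, TT, NPD) tetrad fractions for one interval receiving a
    Poisson(x) number of crossovers per bivalent, no chromatid interference.

    Uses the classical three-state chain: each successive crossover sends
    PD -> TT; TT -> PD, TT, NPD with probabilities 1/4, 1/2, 1/4; NPD -> TT.
    """
    state = [1.0, 0.0, 0.0]
    out = [0.0, 0.0, 0.0]
    pk = math.exp(-x)
    for k in range(kmax + 1):
        if k > 0:
            pk *= x / k
            pd, tt, npd = state
            state = [tt / 4.0, pd + tt / 2.0 + npd, tt / 4.0]
        for s in range(3):
            out[s] += pk * state[s]
    return tuple(out)  # type: ignore[return-value]


def haldane_r(d_cM: float) -> float:
    """Expected recombinant-spore fraction for a d cM interval under the
    no-interference model (mean 2d/100 crossovers per bivalent)."""
    return 0.5 * (1.0 - math.exp(-2.0 * d_cM / 100.0))
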