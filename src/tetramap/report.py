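"""High-level report builders tying the analysis stages together.

These functions reproduce the two published summary tables from the packaged
count fixtures, and build the same table shapes from tetrad-level data
(real or simulated), so simulated and published inputs are interchangeable.
Every filtering decision (tetrads or spores excluded, and why) is logged on
the ``tetramap`` logger.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from . import io as tio
from .mapping import (
    IntervalEstimate,
    SporeCounts,
    interference_test,
    map_table,
    perkins_distance,
    random_spore_distance,
    spore_pool_counts,
)
from .sim import build_study_scenario, simulate_tetrads
from .tetrads import (
    MarkerMap,
    Tetrad,
    count_interval_classes,
    select_two_spore_viable,
    viability_distribution,
)
from .viability import (
    round_half_up,
    spore_viability_percent,
)

__all__ = [
    "load_published_viability",
    "load_published_spore_counts",
    "viability_report",
    "random_spore_map_report",
    "tetrad_map_report",
    "interference_report",
    "simulate_scenario_to_tsv",
    "reproduce_tables",
]

logger = logging.getLogger("tetramap")


def _fixture_path(name: str):
    return resources.files("tetramap.data").joinpath(name)


def load_published_viability() -> pd.DataFrame:
    """Packaged per-strain sporulation and viability-class counts."""
    with resources.as_file(_fixture_path("strain_viability.tsv")) as path:
        return tio.read_viability_table(path)


def load_published_spore_counts() -> pd.DataFrame:
    """Packaged random-spore interval data with ``r`` reconstructed from the
    printed percentage: r = round(pct * t / 100)."""
    with resources.as_file(_fixture_path("random_spore.tsv")) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    df["r"] = [
        round_half_up(pct * t / 100.0)
        for pct, t in zip(df["pct_recombinant"], df["t"])
    ]
    return df


def viability_report(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-strain viability summary (the published table's shape).

    Input: a viability count table (columns ``strain``, ``n4``..``n0``,
    optionally ``sporulation_pct``/``cells_counted``).  Output adds
    ``tetrads_dissected`` and the recomputed ``spore_viability_pct``.
    """
    out = counts.copy()
    out["tetrads_dissected"] = counts[[f"n{k}" for k in range(5)]].sum(axis=1)
    out["spore_viability_pct"] = [
        spore_viability_percent(tio.viability_row_to_distribution(row)).rounded
        for _, row in counts.iterrows()
    ]
    cols = ["strain"]
    if "sporulation_pct" in out.columns:
        cols.append("sporulation_pct")
    cols += ["tetrads_dissected", "n4", "n3", "n2", "n1", "n0", "spore_viability_pct"]
    return out[cols]


def viability_report_from_tetrads(
    per_strain: Mapping[str, Sequence[Tetrad]],
) -> pd.DataFrame:
    """Viability summary computed directly from tetrad records."""
    rows = []
    for strain, tetrads in per_strain.items():
        dist = viability_distribution(tetrads)
        rows.append(
            {
                "strain": strain,
                "tetrads_dissected": dist.total_tetrads,
                **{f"n{k}": dist[k] for k in range(4, -1, -1)},
                "spore_viability_pct": spore_viability_percent(dist).rounded,
            }
        )
    return pd.DataFrame(rows)


def random_spore_map_report(spore_counts: pd.DataFrame) -> pd.DataFrame:
    """Map-distance report from a random-spore count table.

    Input columns: ``strain``, ``interval``, ``r``, ``t``.  Output: the
    long-form map table with a per-strain Total row (sum of interval cM).
    """
    per_strain: Dict[str, List[IntervalEstimate]] = {}
    for _, row in spore_counts.iterrows():
        locusA, _, locusB = row["interval"].partition("-")
        est = random_spore_distance(
            SporeCounts(r=int(row["r"]), t=int(row["t"])),
            interval=(locusA, locusB),
        )
        per_strain.setdefault(row["strain"], []).append(est)
    return map_table(per_strain)


def _intervals(marker_map: MarkerMap) -> List[Tuple[str, str]]:
    names = marker_map.locus_names
    return list(zip(names, names[1:]))


def random_spore_map_report_from_tetrads(
    per_strain: Mapping[str, Sequence[Tetrad]],
    marker_map: MarkerMap,
) -> pd.DataFrame:
    """Random-spore map report from tetrad records: pools viable spores of
    2-spore-viable tetrads (the published filtering rule) and estimates each
    adjacent interval."""
    per_strain_est: Dict[str, List[IntervalEstimate]] = {}
    for strain, tetrads in per_strain.items():
        tetrads = list(tetrads)
        pool = select_two_spore_viable(tetrads)
        logger.info(
            "%s: %d/%d tetrads are 2-spore-viable; random-spore pool of %d spores",
            strain,
            sum(t.n_viable == 2 for t in tetrads),
            len(tetrads),
            len(pool),
        )
        estimates = []
        for locusA, locusB in _intervals(marker_map):
            counts = spore_pool_counts(pool, locusA, locusB)
            if counts.t < len(pool):
                logger.info(
                    "%s %s-%s: %d spores excluded for missing calls",
                    strain, locusA, locusB, len(pool) - counts.t,
                )
            estimates.append(random_spore_distance(counts, (locusA, locusB)))
        per_strain_est[strain] = estimates
    return map_table(per_strain_est)


def tetrad_map_report(
    per_strain: Mapping[str, Sequence[Tetrad]],
    marker_map: MarkerMap,
    n_boot: int = 10_000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Perkins map report from complete (4-spore-viable) tetrads.

    Tetrads with fewer than four viable spores, or with non-2:2 segregation
    at an interval's loci, are excluded from that interval (logged).
    """
    per_strain_est: Dict[str, List[IntervalEstimate]] = {}
    for strain, tetrads in per_strain.items():
        tetrads = list(tetrads)
        estimates = []
        for locusA, locusB in _intervals(marker_map):
            counts = count_interval_classes(tetrads, locusA, locusB)
            excluded = len(tetrads) - counts.n
            if excluded:
                logger.info(
                    "%s %s-%s: %d tetrads unscorable (<4 viable spores or "
                    "non-2:2 segregation)",
                    strain, locusA, locusB, excluded,
                )
            estimates.append(perkins_distance(counts, n_boot=n_boot, rng=seed))
        per_strain_est[strain] = estimates
    return map_table(per_strain_est)


def interference_report(
    per_strain: Mapping[str, Sequence[Tetrad]],
    marker_map: MarkerMap,
    mode: str = "binomial",
) -> pd.DataFrame:
    """NPD observed/expected interference table per strain and interval."""
    rows = []
    for strain, tetrads in per_strain.items():
        for locusA, locusB in _intervals(marker_map):
            counts = count_interval_classes(tetrads, locusA, locusB)
            if counts.n == 0:
                logger.info(
                    "%s %s-%s: no scorable tetrads, skipping interference test",
                    strain, locusA, locusB,
                )
                continue
            res = interference_test(counts, mode=mode)
            rows.append(
                {
                    "strain": strain,
                    "interval": f"{locusA}-{locusB}",
                    "n": res.n,
                    "PD": counts.PD,
                    "TT": counts.TT,
                    "NPD_obs": res.npd_obs,
                    "NPD_exp": res.npd_exp,
                    "ratio": res.ratio,
                    "p_two_sided": res.p_two_sided,
                }
            )
    return pd.DataFrame(rows)


def simulate_scenario_to_tsv(
    scenario: str,
    seed: int,
    path: Union[str, Path],
    n_meioses: int = 300,
) -> List[Tetrad]:
    """Simulate a named scenario and write the tetrad TSV; deterministic
    given (scenario, seed, n_meioses)."""
    config = build_study_scenario(scenario, n_meioses=n_meioses, seed=seed)
    tetrads = simulate_tetrads(config)
    tio.write_tetrads(path, tetrads, config.marker_map)
    return tetrads


def reproduce_tables() -> Dict[str, pd.DataFrame]:
    """Recompute the two published summary tables from the packaged count
    fixtures: the per-strain viability table and the random-spore map table
    (cM, SE and per-strain Total over the three chromosome III intervals)."""
    viability = viability_report(load_published_viability())
    spore = load_published_spore_counts()
    return {
        "viability": viability,
        "map": random_spore_map_report(spore[["strain", "interval", "r", "t"]]),
    }
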