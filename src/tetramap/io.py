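"""Readers and writers for the package's tab-separated dialects.

Three small TSV dialects cover every exchange format:

* **Tetrad tables** -- one row per spore, columns ``tetrad_id``, ``spore_id``,
  ``viable``, then one column per marker locus in map order.  Allele symbols
  are free text mapped onto the parental symbols ``P1``/``P2`` via header
  comment lines of the form ``#phase <locus> <P1allele> <P2allele>``; absent a
  phase line the column must already contain ``P1``/``P2``.  A missing call
  (dead or unscored spore) is written as ``-``.
* **Viability count tables** -- columns ``strain``, ``n4`` .. ``n0`` (tetrads
  with 4..0 viable spores), optionally sporulation columns.
* **Random-spore count tables** -- columns ``strain``, ``interval``, ``r``
  (recombinant colonies), ``t`` (total colonies).

All files are UTF-8, header required, ``#``-prefixed comment lines permitted
before the header.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

import pandas as pd

from .tetrads import (
    P1,
    P2,
    MarkerMap,
    Spore,
    Tetrad,
    ViabilityDistribution,
)

__all__ = [
    "TetradFileError",
    "read_tetrads",
    "write_tetrads",
    "read_viability_table",
    "write_viability_table",
    "read_spore_count_table",
    "write_spore_count_table",
]

MISSING = "-"
_TRUE = {"1", "true", "True", "TRUE", "yes"}
_FALSE = {"0", "false", "False", "FALSE", "no"}


class TetradFileError(ValueError):
    """Malformed tetrad or count table; message names the offending row."""


def _read_lines(path: Union[str, Path]) -> Tuple[Dict[str, Tuple[str, str]], List[List[str]]]:
    """Split a tetrad TSV into phase declarations and data rows (incl. header)."""
    phase: Dict[str, Tuple[str, str]] = {}
    rows: List[List[str]] = []
    with open(path, encoding="utf-8", newline="") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "phase":
                    if len(parts) != 4:
                        raise TetradFileError(
                            f"line {lineno}: phase declaration needs "
                            f"'#phase locus P1allele P2allele'"
                        )
                    phase[parts[1]] = (parts[2], parts[3])
                continue
            rows.append(line.split("\t"))
    return phase, rows


def read_tetrads(path: Union[str, Path], marker_map: MarkerMap) -> List[Tetrad]:
    """Read a tetrad genotype table, validating structure and allele symbols.

    Raises :class:`TetradFileError` for a missing/extra spore row, an unknown
    or missing locus column, or an allele symbol outside the declared phase.
    """
    phase, rows = _read_lines(path)
    if not rows:
        raise TetradFileError(f"{path}: empty file")
    header, *data = rows
    expected = ["tetrad_id", "spore_id", "viable", *marker_map.locus_names]
    if header != expected:
        raise TetradFileError(
            f"{path}: header {header!r} does not match expected {expected!r}"
        )

    def decode_allele(locus: str, raw: str, where: str) -> Optional[str]:
        if raw == MISSING or raw == "":
            return None
        if locus in phase:
            p1, p2 = phase[locus]
            if raw == p1:
                return P1
            if raw == p2:
                return P2
            raise TetradFileError(
                f"{where}: allele {raw!r} at {locus!r} not in declared phase "
                f"({p1!r}, {p2!r})"
            )
        if raw in (P1, P2):
            return raw
        raise TetradFileError(
            f"{where}: allele {raw!r} at {locus!r} is not P1/P2 and no "
            f"#phase line declares {locus!r}"
        )

    by_tetrad: Dict[str, List[Spore]] = {}
    order: List[str] = []
    for i, row in enumerate(data, start=1):
        where = f"{path} data row {i}"
        if len(row) != len(expected):
            raise TetradFileError(
                f"{where}: has {len(row)} fields, expected {len(expected)}"
            )
        tid, sid_raw, viable_raw, *alleles_raw = row
        try:
            sid = int(sid_raw)
        except ValueError as exc:
            raise TetradFileError(f"{where}: bad spore_id {sid_raw!r}") from exc
        if viable_raw in _TRUE:
            viable = True
        elif viable_raw in _FALSE:
            viable = False
        else:
            raise TetradFileError(f"{where}: bad viable flag {viable_raw!r}")
        alleles = {
            locus: decode_allele(locus, raw, where)
            for locus, raw in zip(marker_map.locus_names, alleles_raw)
        }
        try:
            spore = Spore(spore_id=sid, viable=viable, alleles=alleles)
        except ValueError as exc:
            raise TetradFileError(f"{where}: {exc}") from exc
        if tid not in by_tetrad:
            order.append(tid)
        by_tetrad.setdefault(tid, []).append(spore)

    tetrads: List[Tetrad] = []
    for tid in order:
        spores = by_tetrad[tid]
        if len(spores) != 4:
            raise TetradFileError(
                f"{path}: tetrad {tid!r} has {len(spores)} spore rows, need 4"
            )
        if sorted(s.spore_id for s in spores) != [1, 2, 3, 4]:
            raise TetradFileError(
                f"{path}: tetrad {tid!r} spore_ids are not 1,2,3,4"
            )
        tetrads.append(Tetrad(tetrad_id=tid, spores=tuple(spores)))
    return tetrads


def write_tetrads(
    path: Union[str, Path],
    tetrads: Iterable[Tetrad],
    marker_map: MarkerMap,
    phase: Optional[Dict[str, Tuple[str, str]]] = None,
) -> None:
    """Write tetrads in the dialect :func:`read_tetrads` accepts.

    ``phase`` optionally maps locus name to the free-text symbols to emit for
    (P1, P2); by default the canonical ``P1``/``P2`` symbols are written.
    """
    phase = phase or {}
    with open(path, "w", encoding="utf-8", newline="") as handle:
        for locus, (a1, a2) in phase.items():
            handle.write(f"#phase {locus} {a1} {a2}\n")
        header = ["tetrad_id", "spore_id", "viable", *marker_map.locus_names]
        handle.write("\t".join(header) + "\n")
        for tetrad in tetrads:
            for spore in tetrad.spores:
                cells = [tetrad.tetrad_id, str(spore.spore_id), str(int(spore.viable))]
                for locus in marker_map.locus_names:
                    allele = spore.alleles.get(locus)
                    if allele is None:
                        cells.append(MISSING)
                    elif locus in phase:
                        cells.append(phase[locus][0 if allele == P1 else 1])
                    else:
                        cells.append(allele)
                handle.write("\t".join(cells) + "\n")


def read_viability_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a per-strain viability count table into a DataFrame.

    Requires columns ``strain`` and ``n4``..``n0``; passes any extra columns
    (e.g. sporulation counts) through untouched.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"strain": str})
    required = ["strain", "n4", "n3", "n2", "n1", "n0"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TetradFileError(f"{path}: missing columns {missing}")
    for col in required[1:]:
        if (df[col] < 0).any():
            raise TetradFileError(f"{path}: negative count in column {col}")
    return df


def write_viability_table(path: Union[str, Path], df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def viability_row_to_distribution(row: pd.Series) -> ViabilityDistribution:
    """Convert one viability-table row into a :class:`ViabilityDistribution`."""
    return ViabilityDistribution(
        counts={k: int(row[f"n{k}"]) for k in range(5)}
    )


def read_spore_count_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a random-spore count table (strain, interval, r, t)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"strain": str, "interval": str})
    required = ["strain", "interval", "r", "t"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TetradFileError(f"{path}: missing columns {missing}")
    bad = df[(df["r"] < 0) | (df["t"] <= 0) | (df["r"] > df["t"])]
    if len(bad):
        raise TetradFileError(
            f"{path}: rows violate 0 <= r <= t, t > 0: {bad.index.tolist()}"
        )
    return df


def write_spore_count_table(path: Union[str, Path], df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)
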