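"""Hypergeometric over-representation analysis on user-supplied gene sets.

A generic stand-in for annotation-database enrichment: given a query list
(e.g. DEGs), a universe (e.g. all tested genes), and GMT gene sets, each set
is scored by the upper-tail hypergeometric probability of its overlap with
the query, with Benjamini–Hochberg adjustment across sets.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["read_gmt", "write_gmt", "ora"]


class GMTError(ValueError):
    """Raised on a malformed GMT file."""


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Parse a GMT file: name, description, members per tab-separated line.

    Duplicate members within a set are dropped (first occurrence kept).
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise GMTError(f"line {lineno}: expected name, description, members")
        name, desc, members = parts[0], parts[1], parts[2:]
        if name in sets:
            raise GMTError(f"line {lineno}: duplicate set name {name!r}")
        seen: dict[str, None] = {}
        for m in members:
            if m:
                seen.setdefault(m, None)
        if not seen:
            raise GMTError(f"line {lineno}: set {name!r} has no members")
        sets[name] = (desc, list(seen))
    return sets


def write_gmt(sets: dict[str, tuple[str, list[str]]], path: str | Path) -> None:
    lines = [
        "\t".join([name, desc, *members]) for name, (desc, members) in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def ora(
    query: Iterable[str],
    universe: Iterable[str],
    sets: dict[str, tuple[str, list[str]]],
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Over-representation of the query in each gene set.

    Sets are intersected with the universe before testing; p is the
    probability of an overlap at least as large under hypergeometric
    sampling of ``|query|`` genes from the universe; q is the BH adjustment
    across the tested sets. Sets overlapping below ``min_overlap`` are
    excluded from the table.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    m_univ, n_query = len(universe), len(query)
    rows = []
    for name, (desc, members) in sets.items():
        inset = set(members) & universe
        if not inset:
            continue
        overlap = len(inset & query)
        if overlap < min_overlap:
            continue
        p = float(stats.hypergeom.sf(overlap - 1, m_univ, len(inset), n_query))
        rows.append(
            {
                "set": name,
                "description": desc,
                "overlap": overlap,
                "set_size": len(inset),
                "query_size": n_query,
                "universe_size": m_univ,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "set", "description", "overlap", "set_size",
            "query_size", "universe_size", "p",
        ],
    )
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table = table.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        table["q"] = pd.Series(dtype=float)
    return table.set_index("set")
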