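"""Hypergeometric over-representation analysis against GMT gene sets.

A generic replacement for online annotation tools: given a query gene set
(typically the targets of the selected candidate miRNAs) and a GMT
collection, each set is scored with the upper-tail hypergeometric
probability P[X ≥ overlap] of drawing at least the observed overlap when
sampling |query| genes without replacement from the universe, followed by
Benjamini–Hochberg correction across sets.  The universe defaults to the
union of all GMT genes and can be overridden (e.g. intersected with the
network's gene space).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .network import normalize_gene_id

__all__ = [
    "GeneSetCollection",
    "GmtFormatError",
    "hypergeom_ora",
    "read_gmt",
    "write_enrichment",
]

logger = logging.getLogger(__name__)


class GmtFormatError(ValueError):
    """Raised for GMT lines with fewer than three tab-separated fields."""


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe.

    ``sets`` maps set ID → (description, genes); every set is non-empty
    and genes follow the network's normalization (uppercase symbols).
    """

    sets: Mapping[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        empty = [sid for sid, (_, genes) in self.sets.items() if not genes]
        if empty:
            raise ValueError(f"empty gene sets: {empty}")


def read_gmt(
    path: str | Path, universe: Iterable[str] | None = None
) -> GeneSetCollection:
    """Parse a standard GMT file (set ID, description, genes...).

    Genes are normalized and deduplicated within each set.  The universe
    defaults to the union of all genes unless overridden.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"found {len(fields)}"
                )
            set_id, description = fields[0], fields[1]
            genes = frozenset(
                normalize_gene_id(g) for g in fields[2:] if g.strip()
            )
            if not genes:
                raise GmtFormatError(f"{path}:{lineno}: gene set '{set_id}' is empty")
            sets[set_id] = (description, genes)
    if universe is not None:
        background = frozenset(normalize_gene_id(g) for g in universe)
    else:
        background = frozenset().union(*(g for _, g in sets.values())) if sets else frozenset()
    return GeneSetCollection(sets, background)


def hypergeom_ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    fdr_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of *query* in each set.

    Query genes outside the universe are dropped with a warning; an empty
    filtered query yields an empty table.  Rows are sorted by p-value
    (set ID tiebreak) with BH FDR computed across all tested sets.
    """
    columns = [
        "set_id", "description", "overlap_count", "set_size",
        "query_size", "universe_size", "p_value", "bh_fdr",
    ]
    universe = collection.universe
    normalized = {normalize_gene_id(g) for g in query}
    outside = normalized - universe
    if outside:
        logger.warning("%d query genes outside the universe dropped: %s",
                       len(outside), sorted(outside)[:10])
    filtered = normalized & universe
    if not filtered:
        logger.warning("empty query after universe filtering")
        return pd.DataFrame(columns=columns)

    big_n = len(universe)
    small_n = len(filtered)
    rows = []
    for set_id in sorted(collection.sets):
        description, genes = collection.sets[set_id]
        in_universe = genes & universe
        big_k = len(in_universe)
        overlap = len(filtered & in_universe)
        # P[X >= overlap] for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(overlap - 1, big_n, big_k, small_n))
        rows.append(
            {
                "set_id": set_id,
                "description": description,
                "overlap_count": overlap,
                "set_size": big_k,
                "query_size": small_n,
                "universe_size": big_n,
                "p_value": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    table["bh_fdr"] = multipletests(table["p_value"], method=fdr_method)[1]
    table = table.sort_values(["p_value", "set_id"], kind="mergesort")
    return table.reset_index(drop=True)[columns]


def write_enrichment(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
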