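"""Bipartite miRNA–mRNA regulatory network model and the NOD statistic.

A regulatory network is a directed bipartite graph whose edges point from
miRNAs to the genes they repress.  The quantity of interest is each miRNA's
*NOD* ("novel out-degree"): the number of target genes regulated by that
miRNA and by **no other** miRNA in the network.  A gene with regulatory
in-degree exactly 1 is a *unique target*; its sole regulator gains one unit
of NOD.  NOD measures a miRNA's independent regulatory power — positions in
the network where a single deregulated miRNA can perturb a gene with no
compensating regulator.

Networks are built from TSV edge lists (one file per source database, with
a per-file column-name dialect), merged by edge-set union with per-edge
source provenance, and exported as sorted TSV, SIF, or GraphML.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "EdgeListFormatError",
    "NODRecord",
    "RegulatoryNetwork",
    "compute_nod",
    "compute_nod_all",
    "merge_networks",
    "nod_records_frame",
    "normalize_gene_id",
    "normalize_mirna_id",
    "read_edge_list",
    "write_edge_list",
    "write_graphml",
    "write_nod_table",
    "write_sif",
]

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


class EdgeListFormatError(ValueError):
    """Raised when an edge-list file does not match its declared dialect."""


def normalize_mirna_id(raw: str, alias_table: Mapping[str, str] | None = None) -> str:
    """Normalize a miRNA identifier.

    Lowercases, strips a leading species prefix (``hsa-``), and — if an
    alias table is supplied — maps reported names to their official mature
    names (e.g. ``miR-196b`` → ``mir-196b-5p``).  Arm suffixes (``-5p`` /
    ``-3p``) and letter/number suffixes are preserved.  The function is
    idempotent provided the alias table's values are themselves normalized
    official IDs.

    Parameters
    ----------
    raw
        Identifier as it appears in a source file. Must be non-empty.
    alias_table
        Optional mapping from normalized reported IDs to normalized
        official IDs (see :func:`pomanet.fixtures.table1_alias_table`).
    """
    ident = raw.strip().lower()
    if not ident:
        raise ValueError("empty miRNA identifier")
    if ident.startswith("hsa-"):
        ident = ident[4:]
    if alias_table:
        ident = alias_table.get(ident, ident)
    return ident


def normalize_gene_id(raw: str) -> str:
    """Normalize a gene symbol: strip whitespace and uppercase.

    No symbol-alias resolution is attempted; the source databases mix
    symbol conventions and silent alias mapping would change edge counts.
    """
    return raw.strip().upper()


@dataclass(frozen=True)
class NODRecord:
    """Per-miRNA NOD summary.

    ``nod == len(unique_targets)`` and every gene in ``unique_targets`` has
    in-degree exactly 1 in the network the record was computed on.
    ``nod_pvalue`` is attached later by a null model (see
    :mod:`pomanet.poma`) and is ``None`` until then.
    """

    mirna_id: str
    out_degree: int
    nod: int
    unique_targets: frozenset[str]
    nod_pvalue: float | None = None

    def __post_init__(self) -> None:
        if self.nod != len(self.unique_targets):
            raise ValueError(
                f"{self.mirna_id}: nod={self.nod} != |unique_targets|="
                f"{len(self.unique_targets)}"
            )
        if self.nod > self.out_degree:
            raise ValueError(f"{self.mirna_id}: nod exceeds out-degree")
        if self.nod_pvalue is not None and not 0.0 <= self.nod_pvalue <= 1.0:
            raise ValueError(f"{self.mirna_id}: nod_pvalue outside [0,1]")

    def with_pvalue(self, p: float) -> "NODRecord":
        return NODRecord(self.mirna_id, self.out_degree, self.nod,
                         self.unique_targets, float(p))


class RegulatoryNetwork:
    """Deduplicated bipartite miRNA→gene edge set with source provenance.

    The miRNA index (miRNA → target set) and gene index (gene → regulator
    set) are maintained as exact transposes of the edge set; every edge
    carries at least one provenance label.
    """

    def __init__(
        self,
        edges: Iterable[Edge] = (),
        provenance: Mapping[Edge, Iterable[str]] | None = None,
    ) -> None:
        self._edges: set[Edge] = set()
        self._provenance: dict[Edge, tuple[str, ...]] = {}
        self._mirna_index: dict[str, set[str]] = {}
        self._gene_index: dict[str, set[str]] = {}
        provenance = provenance or {}
        for edge in edges:
            mirna, gene = edge
            edge = (str(mirna), str(gene))
            labels = tuple(sorted(set(provenance.get(edge, ("unspecified",)))))
            if not labels:
                labels = ("unspecified",)
            if edge in self._edges:
                merged = sorted(set(self._provenance[edge]) | set(labels))
                self._provenance[edge] = tuple(merged)
                continue
            self._edges.add(edge)
            self._provenance[edge] = labels
            self._mirna_index.setdefault(edge[0], set()).add(edge[1])
            self._gene_index.setdefault(edge[1], set()).add(edge[0])

    # -- read API ---------------------------------------------------------

    @property
    def edges(self) -> frozenset[Edge]:
        return frozenset(self._edges)

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(self._mirna_index)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self._gene_index)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def targets(self, mirna_id: str) -> frozenset[str]:
        if mirna_id not in self._mirna_index:
            raise KeyError(f"miRNA '{mirna_id}' not in network")
        return frozenset(self._mirna_index[mirna_id])

    def regulators(self, gene_id: str) -> frozenset[str]:
        if gene_id not in self._gene_index:
            raise KeyError(f"gene '{gene_id}' not in network")
        return frozenset(self._gene_index[gene_id])

    def sources(self, edge: Edge) -> tuple[str, ...]:
        if edge not in self._provenance:
            raise KeyError(f"edge {edge} not in network")
        return self._provenance[edge]

    def __contains__(self, mirna_id: object) -> bool:
        return mirna_id in self._mirna_index

    def __len__(self) -> int:
        return len(self._mirna_index)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return self._edges == other._edges and self._provenance == other._provenance

    def __repr__(self) -> str:
        return (f"RegulatoryNetwork({len(self._mirna_index)} miRNAs, "
                f"{len(self._gene_index)} genes, {len(self._edges)} edges)")

    # -- derived networks -------------------------------------------------

    def without_mirnas(self, mirna_ids: Iterable[str]) -> "RegulatoryNetwork":
        """Copy of the network with the given miRNAs and their edges removed."""
        drop = set(mirna_ids)
        keep = {e for e in self._edges if e[0] not in drop}
        return RegulatoryNetwork(keep, {e: self._provenance[e] for e in keep})

    def without_edges(self, edges: Iterable[Edge]) -> "RegulatoryNetwork":
        drop = set(edges)
        keep = self._edges - drop
        return RegulatoryNetwork(keep, {e: self._provenance[e] for e in keep})


# -- construction ---------------------------------------------------------

#: Default edge-list dialect: tab-separated with a header line naming the
#: miRNA and gene columns "mirna" and "gene".  Source databases override
#: this with the mappings in ``data/dialects.yaml``.
DEFAULT_DIALECT: dict[str, object] = {"mirna": "mirna", "gene": "gene", "header": True}


def read_edge_list(
    path: str | Path,
    source_label: str,
    dialect: Mapping[str, object] | None = None,
    alias_table: Mapping[str, str] | None = None,
) -> RegulatoryNetwork:
    """Read one miRNA→gene edge-list TSV into a network.

    ``dialect`` names the miRNA and gene columns (strings for named header
    columns, ints for positional columns with ``header: False``).  Lines
    starting with ``#`` are ignored.  Rows with an empty miRNA or gene
    field are dropped with a counted warning; duplicate pairs collapse to
    one edge.  Every edge is tagged with ``source_label``.
    """
    spec = dict(DEFAULT_DIALECT)
    if dialect:
        spec.update(dialect)
    header = 0 if spec.get("header", True) else None
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", header=header, dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("edge list %s is empty; returning empty network", path)
        return RegulatoryNetwork()
    if frame.shape[1] < 2:
        raise EdgeListFormatError(
            f"{path}: edge list needs at least 2 columns, found {frame.shape[1]}"
        )

    def column(key: str) -> pd.Series:
        sel = spec[key]
        if isinstance(sel, bool):  # guard: header flag misused as column
            raise EdgeListFormatError(f"{path}: invalid {key} column selector {sel!r}")
        if isinstance(sel, int):
            if sel >= frame.shape[1]:
                raise EdgeListFormatError(
                    f"{path}: {key} column index {sel} out of range "
                    f"({frame.shape[1]} columns)"
                )
            return frame.iloc[:, sel]
        if sel not in frame.columns:
            raise EdgeListFormatError(f"{path}: missing column '{sel}'")
        return frame[sel]

    mirnas = column("mirna")
    genes = column("gene")
    edges: set[Edge] = set()
    dropped = 0
    for raw_m, raw_g in zip(mirnas, genes):
        if pd.isna(raw_m) or pd.isna(raw_g):
            dropped += 1
            continue
        gene = normalize_gene_id(str(raw_g))
        if not gene or not str(raw_m).strip():
            dropped += 1
            continue
        edges.add((normalize_mirna_id(str(raw_m), alias_table), gene))
    if dropped:
        logger.warning("dropped %d malformed rows from %s", dropped, path)
    return RegulatoryNetwork(edges, {e: (source_label,) for e in edges})


def merge_networks(nets: Sequence[RegulatoryNetwork]) -> RegulatoryNetwork:
    """Union of edge sets; provenance labels are merged and deduplicated.

    Commutative and associative (provenance labels are stored sorted), and
    idempotent: ``merge([A, A]) == A``.
    """
    edges: set[Edge] = set()
    prov: dict[Edge, set[str]] = defaultdict(set)
    for net in nets:
        for edge in net.edges:
            edges.add(edge)
            prov[edge].update(net.sources(edge))
    return RegulatoryNetwork(edges, {e: tuple(sorted(s)) for e, s in prov.items()})


# -- NOD ------------------------------------------------------------------

def compute_nod(net: RegulatoryNetwork, mirna_id: str) -> NODRecord:
    """NOD record for one miRNA: its targets with in-degree 1 in *net*."""
    targets = net.targets(mirna_id)  # raises KeyError for unknown miRNA
    unique = frozenset(g for g in targets if len(net.regulators(g)) == 1)
    return NODRecord(mirna_id, len(targets), len(unique), unique)


def compute_nod_all(net: RegulatoryNetwork) -> list[NODRecord]:
    """NOD records for every miRNA, via a single pass over the gene index.

    Each gene with exactly one regulator contributes one unit of NOD to
    that regulator. Records are returned sorted by miRNA ID.
    """
    unique_by_mirna: dict[str, set[str]] = {m: set() for m in net.mirnas}
    for gene in net.genes:
        regs = net.regulators(gene)
        if len(regs) == 1:
            (sole,) = regs
            unique_by_mirna[sole].add(gene)
    return [
        NODRecord(m, len(net.targets(m)), len(unique_by_mirna[m]),
                  frozenset(unique_by_mirna[m]))
        for m in sorted(net.mirnas)
    ]


def nod_records_frame(records: Iterable[NODRecord]) -> pd.DataFrame:
    rows = [
        {
            "mirna_id": r.mirna_id,
            "out_degree": r.out_degree,
            "nod": r.nod,
            "nod_pvalue": r.nod_pvalue,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["mirna_id", "out_degree", "nod", "nod_pvalue"])


# -- writers --------------------------------------------------------------

def write_edge_list(net: RegulatoryNetwork, path: str | Path) -> None:
    """Sorted (mirna, gene, sources) TSV — diff-stable across runs."""
    with open(path, "w") as fh:
        fh.write("mirna\tgene\tsources\n")
        for mirna, gene in sorted(net.edges):
            fh.write(f"{mirna}\t{gene}\t{','.join(net.sources((mirna, gene)))}\n")


def write_sif(net: RegulatoryNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for mirna, gene in sorted(net.edges):
            fh.write(f"{mirna}\ttargets\t{gene}\n")


def to_graph(net: RegulatoryNetwork) -> nx.DiGraph:
    """networkx view with node attribute ``kind`` and edge attribute ``sources``."""
    graph = nx.DiGraph()
    for mirna in sorted(net.mirnas):
        graph.add_node(mirna, kind="mirna")
    for gene in sorted(net.genes):
        graph.add_node(gene, kind="gene")
    for mirna, gene in sorted(net.edges):
        graph.add_edge(mirna, gene, sources=",".join(net.sources((mirna, gene))))
    return graph


def write_graphml(net: RegulatoryNetwork, path: str | Path) -> None:
    nx.write_graphml(to_graph(net), path)


def write_nod_table(records: Iterable[NODRecord], path: str | Path) -> None:
    frame = nod_records_frame(records)
    frame.to_csv(path, sep="\t", index=False)
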