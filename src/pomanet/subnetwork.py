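"""Candidate-specific subnetwork extraction and accounting.

Given a set of candidate miRNAs, the subnetwork is the edge-induced
subgraph on those miRNAs and all their targets in the parent network.
Each edge carries a uniqueness flag marking the wet-lab-checkable
positions: by default a gene is flagged unique when its in-degree in the
**parent** network is exactly 1 (strictest reading of "exclusively
regulated"); ``uniqueness="subnetwork"`` instead judges uniqueness among
the candidates only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import networkx as nx

from .network import Edge, RegulatoryNetwork
from .poma import CandidateSet

__all__ = [
    "Subnetwork",
    "SubnetworkCounts",
    "accounting",
    "extract_subnetwork",
    "write_subnetwork_graphml",
    "write_subnetwork_sif",
    "write_subnetwork_tsv",
]


@dataclass
class Subnetwork:
    parent: RegulatoryNetwork
    mirnas: tuple[str, ...]
    edges: frozenset[Edge]
    genes: frozenset[str]
    unique_flags: dict[Edge, bool]

    def __post_init__(self) -> None:
        if self.genes != {g for _, g in self.edges}:
            raise ValueError("gene set inconsistent with edge targets")


class SubnetworkCounts(NamedTuple):
    n_mirnas: int
    n_genes: int
    n_edges: int
    n_unique_genes: int


def _candidate_ids(candidates: CandidateSet | Iterable[str]) -> list[str]:
    if isinstance(candidates, CandidateSet):
        return list(candidates.selected_ids)
    return list(candidates)


def extract_subnetwork(
    net: RegulatoryNetwork,
    candidates: CandidateSet | Iterable[str],
    uniqueness: str = "parent",
) -> Subnetwork:
    """Edge-induced subgraph on the candidate miRNAs.

    ``uniqueness="parent"``: an edge is flagged unique iff its gene has
    in-degree 1 in the parent network (a gene unique among the candidates
    but shared in the parent is flagged False).
    ``uniqueness="subnetwork"``: flagged iff exactly one candidate
    regulates the gene.
    """
    if uniqueness not in {"parent", "subnetwork"}:
        raise ValueError("uniqueness must be 'parent' or 'subnetwork'")
    ids = sorted(set(_candidate_ids(candidates)))
    for mirna in ids:
        if mirna not in net:
            raise KeyError(f"candidate miRNA '{mirna}' not in network")
    edges = frozenset((m, g) for m in ids for g in net.targets(m))
    genes = frozenset(g for _, g in edges)
    if uniqueness == "parent":
        flags = {e: len(net.regulators(e[1])) == 1 for e in edges}
    else:
        candidate_regs = {g: sum(1 for m in ids if g in net.targets(m))
                          for g in genes}
        flags = {e: candidate_regs[e[1]] == 1 for e in edges}
    return Subnetwork(net, tuple(ids), edges, genes, flags)


def accounting(sub: Subnetwork) -> SubnetworkCounts:
    """(miRNA count, distinct gene count, pair count, unique-gene count)."""
    unique_genes = {g for (m, g), flag in sub.unique_flags.items() if flag}
    return SubnetworkCounts(
        n_mirnas=len(sub.mirnas),
        n_genes=len(sub.genes),
        n_edges=len(sub.edges),
        n_unique_genes=len(unique_genes),
    )


def write_subnetwork_tsv(sub: Subnetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\tgene\tunique\n")
        for mirna, gene in sorted(sub.edges):
            flag = "true" if sub.unique_flags[(mirna, gene)] else "false"
            fh.write(f"{mirna}\t{gene}\t{flag}\n")


def write_subnetwork_sif(sub: Subnetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for mirna, gene in sorted(sub.edges):
            fh.write(f"{mirna}\ttargets\t{gene}\n")


def write_subnetwork_graphml(sub: Subnetwork, path: str | Path) -> None:
    graph = nx.DiGraph()
    for mirna in sub.mirnas:
        graph.add_node(mirna, kind="mirna")
    unique_genes = {g for (m, g), flag in sub.unique_flags.items() if flag}
    for gene in sorted(sub.genes):
        graph.add_node(gene, kind="gene", unique=gene in unique_genes)
    for mirna, gene in sorted(sub.edges):
        graph.add_edge(mirna, gene, unique=sub.unique_flags[(mirna, gene)])
    nx.write_graphml(graph, path)
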