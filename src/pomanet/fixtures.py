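"""Packaged fixtures: curated-table transcriptions and toy networks.

Two literature tables ship with the package as TSVs:

* ``table1_literature_mirnas.tsv`` — 30 miRNAs curated from published
  chemoradiotherapy-response studies, with their reported and official
  mature IDs and the NOD value each attains in the integrated network.
* ``table2_candidates.tsv`` — the nine candidate biomarkers with their DE
  p-value, target count, NOD value and NOD p-value.

The source target databases are version-dependent and not bundled, so the
full integrated network behind those NOD values is not reconstructable at
desk scale.  Instead, deterministic *toy* networks realizing the printed
per-miRNA NOD (and, for the candidate table, out-degree) values are
constructed here by a reservation scheme: each miRNA owns a block of
synthetic unique genes (in-degree 1) plus shared genes of in-degree ≥ 2.
The printed NOD p-values are consumed as a fixture and are not
re-derived; the null model behind them is not specified in the source
tables.
"""

from __future__ import annotations

import io
from importlib.resources import files

import pandas as pd
import yaml

from .network import (
    NODRecord,
    RegulatoryNetwork,
    normalize_mirna_id,
)
from .poma import CandidateSet

__all__ = [
    "database_dialects",
    "load_table1",
    "load_table2",
    "table1_alias_table",
    "table1_toy_network",
    "table2_candidates",
    "table2_toy_network",
]

_DATA = files("pomanet") / "data"


def _read_packaged_tsv(name: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO((_DATA / name).read_text()), sep="\t")


def load_table1() -> pd.DataFrame:
    """The 30 literature-curated miRNAs with their NOD annotation."""
    return _read_packaged_tsv("table1_literature_mirnas.tsv")


def load_table2() -> pd.DataFrame:
    """The nine candidate biomarkers with printed DE and NOD statistics."""
    return _read_packaged_tsv("table2_candidates.tsv")


def table1_alias_table() -> dict[str, str]:
    """Reported→official miRNA ID mapping (normalized on both sides).

    E.g. ``mir-196b → mir-196b-5p``.  Identity pairs are dropped so the
    mapping stays idempotent under :func:`normalize_mirna_id`.
    """
    table = load_table1()
    alias: dict[str, str] = {}
    for _, row in table.iterrows():
        reported = normalize_mirna_id(row["reported_id"])
        official = normalize_mirna_id(row["official_id"])
        if reported != official:
            alias[reported] = official
    return alias


def database_dialects() -> dict[str, dict]:
    """Edge-list column mappings for common target-database exports."""
    return yaml.safe_load((_DATA / "dialects.yaml").read_text())


def table1_toy_network() -> RegulatoryNetwork:
    """Deterministic toy network realizing the curated miRNAs' NOD values.

    Each of the 30 miRNAs owns exactly ``nod`` synthetic unique genes
    plus three genes shared by all 30 (in-degree 30, hence never unique),
    so ``compute_nod_all`` reproduces the printed NOD column exactly and
    every out-degree strictly exceeds the NOD.
    """
    table = load_table1()
    edges: set[tuple[str, str]] = set()
    shared = ("SHARED-A", "SHARED-B", "SHARED-C")
    for i, row in table.iterrows():
        mirna = normalize_mirna_id(row["official_id"])
        for k in range(int(row["nod"])):
            edges.add((mirna, f"UG{i:02d}K{k:02d}"))
        for gene in shared:
            edges.add((mirna, gene))
    return RegulatoryNetwork(edges, {e: ("table1-toy",) for e in edges})


def table2_toy_network() -> RegulatoryNetwork:
    """Deterministic toy network realizing the candidates' NOD *and*
    out-degree values.

    Each candidate owns ``nod`` unique genes; its remaining
    ``n_targets − nod`` edges point at shared genes, each shared gene
    being targeted by exactly two *different* candidates (pairing the
    first half of the shared-slot list against the second half — no
    candidate's slots span more than half the list, so the two slots of a
    gene always belong to different miRNAs).  The total edge count equals
    the sum of the printed target counts.
    """
    table = load_table2()
    edges: set[tuple[str, str]] = set()
    slots: list[str] = []
    for i, row in table.iterrows():
        mirna = str(row["mirna_id"])
        nod = int(row["nod"])
        for k in range(nod):
            edges.add((mirna, f"U{i:02d}K{k:03d}"))
        slots.extend([mirna] * (int(row["n_targets"]) - nod))
    if len(slots) % 2:
        raise AssertionError("shared-slot count must be even")
    half = len(slots) // 2
    for j in range(half):
        first, second = slots[j], slots[half + j]
        if first == second:
            raise AssertionError("shared gene assigned twice to one candidate")
        gene = f"S{j:03d}"
        edges.add((first, gene))
        edges.add((second, gene))
    return RegulatoryNetwork(edges, {e: ("table2-toy",) for e in edges})


def table2_candidates(alpha: float = 0.05) -> CandidateSet:
    """Candidate set built from the printed table (fixture mode).

    NOD records come from :func:`table2_toy_network` (so unique-target
    sets are concrete and consistent); the DE and NOD p-values are the
    printed ones.  Selection applies ``nod_p_value < alpha`` with
    NOD ≥ 1, mirroring the pipeline's thresholding stage.
    """
    table = load_table2()
    net = table2_toy_network()
    de_pvalues = dict(zip(table["mirna_id"], table["de_p_value"]))
    nod_pvalues = dict(zip(table["mirna_id"], table["nod_p_value"]))

    records = []
    for mirna in table["mirna_id"]:
        targets = net.targets(mirna)
        unique = frozenset(
            g for g in targets if len(net.regulators(g)) == 1
        )
        records.append(
            NODRecord(mirna, len(targets), len(unique), unique,
                      float(nod_pvalues[mirna]))
        )
    records = tuple(
        sorted(records, key=lambda r: (-r.nod, r.nod_pvalue, r.mirna_id))
    )
    selected = tuple(
        r for r in records if r.nod >= 1 and r.nod_pvalue < alpha
    )
    provenance = {
        "mode": "printed-table fixture",
        "counts": {"n_records": len(records), "n_candidates": len(selected)},
        "note": "NOD p-values transcribed, not re-derived",
    }
    return CandidateSet(records, selected, de_pvalues, provenance)
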