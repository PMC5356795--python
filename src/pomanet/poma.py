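"""Candidate biomarker selection: DE filtering × NOD significance.

The selection stage composes four steps: differential expression between
responders and non-responders, mapping the DE miRNAs onto the regulatory
network, computing each mapped miRNA's NOD, and attaching a NOD
significance level from one of two null models:

``empirical_tail``
    Deterministic rank-based tail over the network's own NOD
    distribution: ``p(m) = (1 + #{miRNAs with NOD ≥ NOD(m)}) / (1 + M)``
    for ``M`` network miRNAs.  The count includes ``m`` itself, so p is
    never 0 and the miRNA with the strictly largest NOD gets
    ``2 / (1 + M)``.  Higher NOD never yields a larger p-value.

``rewire_permutation``
    Degree-preserving bipartite randomization (curveball trades, which
    preserve every miRNA's out-degree and every gene's in-degree) with
    ``p(m) = (1 + #{permutations with NOD*(m) ≥ NOD(m)}) / (1 + n_perm)``.
    Because gene in-degrees are preserved, the identity of the network's
    unique genes is invariant and only their assignment to miRNAs is
    randomized — the null asks whether a miRNA holds more unique targets
    than a random degree-matched reallocation would give it.

A miRNA is selected as a candidate biomarker when it is DE, present in the
network, has NOD ≥ 1, and its NOD p-value is below ``nod_alpha``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .de_analysis import ExpressionMatrix, select_de
from .network import NODRecord, RegulatoryNetwork, compute_nod_all

__all__ = [
    "CandidateSet",
    "PomaConfig",
    "map_de_to_network",
    "nod_null_pvalues",
    "run_poma",
    "write_candidates",
]

logger = logging.getLogger(__name__)

_NULL_METHODS = {"empirical_tail", "rewire_permutation"}


@dataclass(frozen=True)
class PomaConfig:
    """Tunable parameters of the selection pipeline.

    ``null_method`` defaults to the deterministic empirical tail; the
    rewiring null is preferred when several miRNAs are expected to share
    the top of the NOD distribution, since a rank-based tail cannot push
    the k-th ranked miRNA below ``(1 + k) / (1 + M)``.
    """

    de_p_threshold: float = 0.05
    fc_threshold: float = 2.0
    nod_alpha: float = 0.05
    null_method: str = "empirical_tail"
    n_permutations: int = 1000
    seed: int = 0
    t_variant: str = "student"

    def __post_init__(self) -> None:
        if not 0 < self.de_p_threshold < 1:
            raise ValueError("de_p_threshold must lie in (0, 1)")
        if not 0 <= self.nod_alpha < 1:
            raise ValueError("nod_alpha must lie in [0, 1)")
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be positive")
        if self.null_method not in _NULL_METHODS:
            raise ValueError(f"null_method must be one of {sorted(_NULL_METHODS)}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if self.null_method == "rewire_permutation" and self.n_permutations < 100:
            logger.warning(
                "n_permutations=%d < 100; permutation p-values will be coarse",
                self.n_permutations,
            )


@dataclass
class CandidateSet:
    """Outcome of the selection stage.

    ``records`` hold one NOD record (with p-value) per DE miRNA found in
    the network, ordered by NOD descending, then p ascending, then ID;
    ``selected`` is the subset passing ``nod_alpha`` with NOD ≥ 1.
    ``provenance`` echoes the configuration and stage-by-stage counts.
    """

    records: tuple[NODRecord, ...]
    selected: tuple[NODRecord, ...]
    de_pvalues: Mapping[str, float]
    provenance: dict
    de_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ids = {r.mirna_id for r in self.records}
        if not {r.mirna_id for r in self.selected} <= ids:
            raise ValueError("selected records not a subset of records")
        if any(r.nod < 1 for r in self.selected):
            raise ValueError("selected candidate with NOD < 1")

    @property
    def selected_ids(self) -> list[str]:
        return [r.mirna_id for r in self.selected]

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "mirna_id": r.mirna_id,
                "de_p_value": self.de_pvalues.get(r.mirna_id),
                "n_targets": r.out_degree,
                "nod": r.nod,
                "nod_p_value": r.nod_pvalue,
            }
            for r in self.selected
        ]
        return pd.DataFrame(
            rows,
            columns=["mirna_id", "de_p_value", "n_targets", "nod", "nod_p_value"],
        )


def map_de_to_network(
    de: pd.DataFrame, net: RegulatoryNetwork
) -> tuple[list[str], list[str]]:
    """Partition the selected DE miRNAs by network membership.

    Returns ``(mapped, unmapped)``, both sorted.  Unmapped miRNAs are
    logged, never silently dropped.
    """
    de_ids = sorted(de.loc[de["selected"], "mirna_id"])
    mapped = [m for m in de_ids if m in net]
    unmapped = [m for m in de_ids if m not in net]
    if unmapped:
        logger.info("%d DE miRNAs not present in the network: %s",
                    len(unmapped), unmapped)
    return mapped, unmapped


# -- null models ----------------------------------------------------------

def _curveball_trades(
    target_sets: list[set[str]], n_trades: int, rng: np.random.Generator
) -> None:
    """In-place curveball trades on a list of per-miRNA target sets.

    Each trade picks two miRNAs and randomly re-deals the symmetric
    difference of their target sets, keeping both set sizes fixed.  Every
    gene stays targeted by the same total number of miRNAs, so both
    degree sequences of the bipartite graph are preserved and no
    duplicate edges can arise.
    """
    n = len(target_sets)
    if n < 2:
        return
    for _ in range(n_trades):
        i = int(rng.integers(n))
        j = int(rng.integers(n - 1))
        if j >= i:
            j += 1
        a, b = target_sets[i], target_sets[j]
        a_only = a - b
        b_only = b - a
        if not a_only or not b_only:
            continue
        pool = sorted(a_only | b_only)
        rng.shuffle(pool)
        shared = a & b
        k = len(a_only)
        target_sets[i] = shared | set(pool[:k])
        target_sets[j] = shared | set(pool[k:])


def nod_null_pvalues(
    net: RegulatoryNetwork,
    focal: Sequence[str],
    method: str = "empirical_tail",
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """NOD significance for the focal miRNAs under the chosen null.

    Both estimators use +1 smoothing so p is never exactly 0.  The
    empirical tail is deterministic and ignores ``n_permutations`` and
    ``seed``; the rewiring null samples a curveball Markov chain (burn-in
    10·M trades, thinning 2·M trades between samples for M miRNAs) and is
    reproducible given the seed.
    """
    if method not in _NULL_METHODS:
        raise ValueError(f"null method must be one of {sorted(_NULL_METHODS)}")
    for mirna in focal:
        if mirna not in net:
            raise KeyError(f"focal miRNA '{mirna}' not in network")
    if not focal:
        return {}

    records = {r.mirna_id: r for r in compute_nod_all(net)}

    if method == "empirical_tail":
        nods = np.array([r.nod for r in records.values()])
        total = len(nods)
        return {
            m: float((1 + int((nods >= records[m].nod).sum())) / (1 + total))
            for m in focal
        }

    # rewire_permutation
    mirnas = sorted(net.mirnas)
    index = {m: i for i, m in enumerate(mirnas)}
    # gene in-degrees are invariant under curveball trades, so the set of
    # unique genes is fixed; only their ownership is randomized
    unique_genes = frozenset(g for g in net.genes if len(net.regulators(g)) == 1)
    observed = {m: records[m].nod for m in focal}
    target_sets = [set(net.targets(m)) for m in mirnas]

    rng = np.random.default_rng(seed)
    n = len(mirnas)
    _curveball_trades(target_sets, 10 * n, rng)  # burn-in
    exceed = {m: 0 for m in focal}
    for _ in range(n_permutations):
        _curveball_trades(target_sets, 2 * n, rng)
        for m in focal:
            if len(target_sets[index[m]] & unique_genes) >= observed[m]:
                exceed[m] += 1
    return {
        m: float((1 + exceed[m]) / (1 + n_permutations)) for m in focal
    }


# -- pipeline -------------------------------------------------------------

def run_poma(
    expr: ExpressionMatrix,
    net: RegulatoryNetwork,
    config: PomaConfig | None = None,
) -> CandidateSet:
    """Full selection pipeline: DE → map → NOD → NOD p-value → threshold.

    NOD is computed on the full network (uniqueness judged against all
    network miRNAs, not only the DE ones).  Deterministic given the
    config seed.  An empty mapped set yields an empty candidate set with
    a warning, not an exception.
    """
    config = config or PomaConfig()
    de = select_de(expr, config.de_p_threshold, config.fc_threshold,
                   config.t_variant)
    mapped, unmapped = map_de_to_network(de, net)
    de_pvalues = dict(zip(de["mirna_id"], de["p_value"]))

    provenance = {
        "config": asdict(config),
        "counts": {
            "n_mirnas_expression": len(expr.mirna_ids),
            "n_samples": len(expr.values.columns),
            "n_network_mirnas": len(net.mirnas),
            "n_network_genes": len(net.genes),
            "n_network_edges": net.n_edges,
            "n_de_selected": int(de["selected"].sum()),
            "n_mapped": len(mapped),
            "n_unmapped": len(unmapped),
        },
        "unmapped": unmapped,
    }

    if not mapped:
        logger.warning("no DE miRNA maps onto the network; empty candidate set")
        provenance["counts"]["n_candidates"] = 0
        return CandidateSet((), (), de_pvalues, provenance, de)

    pvals = nod_null_pvalues(net, mapped, config.null_method,
                             config.n_permutations, config.seed)
    all_records = {r.mirna_id: r for r in compute_nod_all(net)}
    records = tuple(
        sorted(
            (all_records[m].with_pvalue(pvals[m]) for m in mapped),
            key=lambda r: (-r.nod, r.nod_pvalue, r.mirna_id),
        )
    )
    selected = tuple(
        r for r in records if r.nod >= 1 and r.nod_pvalue < config.nod_alpha
    )
    provenance["counts"]["n_candidates"] = len(selected)
    return CandidateSet(records, selected, de_pvalues, provenance, de)


def write_candidates(candidates: CandidateSet, path: str | Path) -> None:
    """TSV of selected candidates plus a ``.provenance.json`` sidecar."""
    path = Path(path)
    candidates.frame().to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    with open(sidecar, "w") as fh:
        json.dump(candidates.provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
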