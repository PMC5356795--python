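import numpy as np
import pandas as pd
import pytest

from pomanet import ExpressionMatrix, RegulatoryNetwork
from pomanet.simulate import recovery_benchmark


def random_bipartite(rng, n_mirna, n_gene, p):
    """Random bipartite miRNA->gene network via independent edge coins."""
    mirnas = [f"mir-{i}" for i in range(n_mirna)]
    genes = [f"G{j}" for j in range(n_gene)]
    mask = rng.random((n_mirna, n_gene)) < p
    edges = {(mirnas[i], genes[j]) for i, j in zip(*np.nonzero(mask))}
    return RegulatoryNetwork(edges)


def brute_force_nod(edges):
    """Oracle: per-gene regulator count by scanning the raw edge list."""
    edges = list(edges)
    genes = {g for _, g in edges}
    regulator_count = {
        g: sum(1 for _, gene in edges if gene == g) for g in genes
    }
    nod = {}
    for mirna in {m for m, _ in edges}:
        targets = [g for m, g in edges if m == mirna]
        nod[mirna] = sum(1 for g in targets if regulator_count[g] == 1)
    return nod


@pytest.fixture
def tiny_expr():
    """4 miRNAs x 6 samples, log2 scale, one clear shift in mir-a."""
    rng = np.random.default_rng(42)
    samples = ["R1", "R2", "R3", "N1", "N2", "N3"]
    values = pd.DataFrame(
        rng.normal(8.0, 0.3, size=(4, 6)),
        index=["mir-a", "mir-b", "mir-c", "mir-d"],
        columns=samples,
    )
    values.loc["mir-a", ["R1", "R2", "R3"]] += 3.0
    groups = {s: "responder" if s.startswith("R") else "non_responder"
              for s in samples}
    return ExpressionMatrix(values, groups, scale="log2")


@pytest.fixture(scope="session")
def benchmark_results():
    """Shared 20-seed recovery run of the standard planted benchmark."""
    return recovery_benchmark(n_seeds=20, base_seed=101)
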