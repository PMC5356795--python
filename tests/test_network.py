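"""Network model, ID normalization, merging, and the NOD statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pomanet import (
    RegulatoryNetwork,
    compute_nod,
    compute_nod_all,
    merge_networks,
    normalize_mirna_id,
    read_edge_list,
    write_edge_list,
)
from pomanet.fixtures import table1_alias_table
from pomanet.network import EdgeListFormatError, write_graphml, write_sif

from conftest import brute_force_nod, random_bipartite


class TestNormalizeMirnaId:
    @pytest.mark.parametrize(
        "raw, alias, expected",
        [
            ("miR-630", True, "mir-630"),
            ("miR-196b", True, "mir-196b-5p"),  # reported -> official arm
            ("miR-451", True, "mir-451a"),
            ("hsa-miR-765", False, "mir-765"),
            ("mir-765", False, "mir-765"),
            ("let-7a", True, "let-7a-5p"),
            ("HSA-miR-21", False, "mir-21"),
        ],
    )
    def test_normalization(self, raw, alias, expected):
        table = table1_alias_table() if alias else None
        assert normalize_mirna_id(raw, table) == expected

    def test_idempotent(self):
        table = table1_alias_table()
        for raw in ["miR-196b", "hsa-miR-765", "let-7g", "miR-124"]:
            once = normalize_mirna_id(raw, table)
            assert normalize_mirna_id(once, table) == once

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_mirna_id("   ")


class TestReadEdgeList:
    def test_duplicate_rows_deduplicated(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("mirna\tgene\nmiR-1\tTP53\nmiR-1\tTP53\nmiR-2\tKRAS\n")
        net = read_edge_list(path, "db1")
        assert net.n_edges == 2
        assert net.sources(("mir-1", "TP53")) == ("db1",)

    def test_cross_file_normalization_consistency(self, tmp_path):
        a = tmp_path / "a.tsv"
        b = tmp_path / "b.tsv"
        a.write_text("mirna\tgene\nhsa-miR-630\tBCL2\n")
        b.write_text("mirna\tgene\nmiR-630\tBCL2\n")
        net_a = read_edge_list(a, "a")
        net_b = read_edge_list(b, "b")
        assert net_a.edges == net_b.edges == {("mir-630", "BCL2")}

    def test_row_order_irrelevant_and_matches_set_oracle(self, tmp_path):
        rng = np.random.default_rng(0)
        rows = [(f"miR-{rng.integers(4)}", f"G{rng.integers(6)}")
                for _ in range(10)]
        fwd = tmp_path / "fwd.tsv"
        rev = tmp_path / "rev.tsv"
        body = "".join(f"{m}\t{g}\n" for m, g in rows)
        rev_body = "".join(f"{m}\t{g}\n" for m, g in reversed(rows))
        fwd.write_text("mirna\tgene\n" + body)
        rev.write_text("mirna\tgene\n" + rev_body)
        oracle = {(m.lower(), g.upper()) for m, g in rows}
        assert read_edge_list(fwd, "x").edges == oracle
        assert read_edge_list(fwd, "x") == read_edge_list(rev, "x")

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("a\tb\nmiR-1\tTP53\n")
        with pytest.raises(EdgeListFormatError, match="mirna"):
            read_edge_list(path, "db")

    def test_empty_file_gives_empty_network(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("")
        assert read_edge_list(path, "db").n_edges == 0

    def test_malformed_rows_dropped(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("mirna\tgene\nmiR-1\tTP53\nmiR-2\t\n# comment\n")
        net = read_edge_list(path, "db")
        assert net.edges == {("mir-1", "TP53")}

    def test_positional_dialect(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("miR-9\tPTEN\nmiR-9\tTP53\n")
        net = read_edge_list(path, "db",
                             {"mirna": 0, "gene": 1, "header": False})
        assert net.n_edges == 2


class TestMerge:
    def test_union_with_shared_provenance(self):
        a = RegulatoryNetwork({("x", "G1")}, {("x", "G1"): ("dbA",)})
        b = RegulatoryNetwork({("x", "G1"), ("y", "G2")},
                              {("x", "G1"): ("dbB",), ("y", "G2"): ("dbB",)})
        merged = merge_networks([a, b])
        assert merged.n_edges == 2
        assert merged.sources(("x", "G1")) == ("dbA", "dbB")

    def test_idempotent_and_commutative(self):
        a = RegulatoryNetwork({("x", "G1")}, {("x", "G1"): ("dbA",)})
        b = RegulatoryNetwork({("y", "G2")}, {("y", "G2"): ("dbB",)})
        assert merge_networks([a, a]) == a
        assert merge_networks([a, b]) == merge_networks([b, a])
        assert merge_networks([]).n_edges == 0

    def test_union_size_matches_set_oracle(self):
        rng = np.random.default_rng(3)
        nets = [random_bipartite(rng, 8, 12, 0.2) for _ in range(3)]
        merged = merge_networks(nets)
        oracle = set().union(*(n.edges for n in nets))
        assert merged.edges == oracle


class TestNOD:
    def test_sole_mirna_has_nod_equal_out_degree(self):
        net = RegulatoryNetwork({("m", "G1"), ("m", "G2"), ("m", "G3")})
        rec = compute_nod(net, "m")
        assert rec.nod == rec.out_degree == 3
        assert rec.unique_targets == {"G1", "G2", "G3"}

    def test_fully_shared_targets_have_nod_zero(self):
        net = RegulatoryNetwork(
            {("m1", "G1"), ("m1", "G2"), ("m2", "G1"), ("m2", "G2")}
        )
        assert compute_nod(net, "m1").nod == 0
        assert compute_nod(net, "m2").nod == 0

    def test_unknown_mirna_raises_named_key_error(self):
        net = RegulatoryNetwork({("m", "G1")})
        with pytest.raises(KeyError, match="ghost"):
            compute_nod(net, "ghost")

    def test_matches_brute_force_oracle_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            net = random_bipartite(
                rng,
                int(rng.integers(3, 30)),
                int(rng.integers(5, 80)),
                float(rng.uniform(0.02, 0.2)),
            )
            oracle = brute_force_nod(net.edges)
            records = {r.mirna_id: r for r in compute_nod_all(net)}
            assert {m: r.nod for m, r in records.items()} == oracle
            for rec in records.values():
                assert rec == compute_nod(net, rec.mirna_id)

    def test_conservation_laws(self):
        rng = np.random.default_rng(5)
        net = random_bipartite(rng, 20, 100, 0.08)
        records = compute_nod_all(net)
        in_degree_one = sum(
            1 for g in net.genes if len(net.regulators(g)) == 1
        )
        assert sum(r.nod for r in records) == in_degree_one
        assert sum(r.out_degree for r in records) == net.n_edges
        assert sum(r.nod for r in records) <= len(net.genes)

    def test_removing_other_mirnas_never_decreases_nod(self):
        rng = np.random.default_rng(9)
        net = random_bipartite(rng, 10, 40, 0.12)
        mirnas = sorted(net.mirnas)
        base = {r.mirna_id: r.nod for r in compute_nod_all(net)}
        for removed in mirnas:
            reduced = net.without_mirnas([removed])
            for rec in compute_nod_all(reduced):
                assert rec.nod >= base[rec.mirna_id]

    def test_removing_own_edge_never_increases_nod(self):
        rng = np.random.default_rng(13)
        net = random_bipartite(rng, 6, 20, 0.2)
        base = {r.mirna_id: r for r in compute_nod_all(net)}
        for edge in sorted(net.edges)[:15]:
            reduced = net.without_edges([edge])
            for rec in compute_nod_all(reduced):
                if rec.mirna_id == edge[0]:
                    assert rec.nod <= base[rec.mirna_id].nod
                assert rec.nod <= rec.out_degree

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        edges_a=st.sets(
            st.tuples(st.sampled_from(["m1", "m2", "m3"]),
                      st.sampled_from([f"G{i}" for i in range(8)])),
            min_size=1, max_size=15,
        ),
        edges_b=st.sets(
            st.tuples(st.sampled_from(["m4", "m5"]),
                      st.sampled_from([f"G{i}" for i in range(8)])),
            max_size=10,
        ),
    )
    def test_merge_monotonicity(self, edges_a, edges_b):
        """Adding foreign regulators can only remove target uniqueness."""
        a = RegulatoryNetwork(edges_a)
        b = RegulatoryNetwork(edges_b)
        merged = merge_networks([a, b])
        nod_a = {r.mirna_id: r.nod for r in compute_nod_all(a)}
        for rec in compute_nod_all(merged):
            if rec.mirna_id in nod_a:
                assert rec.nod <= nod_a[rec.mirna_id]


class TestExports:
    def test_edge_list_roundtrip_sorted(self, tmp_path):
        net = RegulatoryNetwork(
            {("mir-b", "G2"), ("mir-a", "G1")},
            {("mir-b", "G2"): ("x",), ("mir-a", "G1"): ("y", "x")},
        )
        path = tmp_path / "out.tsv"
        write_edge_list(net, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "mirna\tgene\tsources"
        assert lines[1] == "mir-a\tG1\tx,y"
        reread = read_edge_list(path, "z")
        assert reread.edges == net.edges

    def test_sif_and_graphml(self, tmp_path):
        import networkx as nx

        net = RegulatoryNetwork({("mir-a", "G1"), ("mir-a", "G2")})
        sif = tmp_path / "net.sif"
        gml = tmp_path / "net.graphml"
        write_sif(net, sif)
        assert sif.read_text().splitlines() == [
            "mir-a\ttargets\tG1", "mir-a\ttargets\tG2",
        ]
        write_graphml(net, gml)
        graph = nx.read_graphml(gml)
        kinds = nx.get_node_attributes(graph, "kind")
        assert kinds == {"mir-a": "mirna", "G1": "gene", "G2": "gene"}
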