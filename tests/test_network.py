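"""Co-regulatory network assembly, family collapsing, SIF/GraphML export."""

import networkx as nx
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from corewire import network
from corewire.io import GeneSet, GeneSetCollection


def enr_row(cluster, regulator, kind, p, family=None):
    return {"cluster": cluster, "regulator": regulator, "kind": kind,
            "family": family, "k": 3, "m": 10, "K": 5, "N": 100,
            "odds_ratio": 5.0, "p": p, "significant": True}


def edge_multiset(net):
    """Canonical multiset of typed edges (ppi endpoints sorted)."""
    out = []
    for u, v, d in net.graph.edges(data=True):
        if d["edge_type"] == "ppi":
            u, v = sorted((u, v))
        out.append((u, d["edge_type"], v))
    return sorted(out)


class TestCollapseFamilies:
    def test_keeps_smallest_p_in_family(self):
        df = pd.DataFrame([
            enr_row("UUu", "miR-300", "miRNA", 0.004,
                    family="miR-300/381"),
            enr_row("UUu", "miR-381", "miRNA", 0.007,
                    family="miR-300/381")])
        out = network.collapse_families(df)
        assert list(out["regulator"]) == ["miR-300"]

    def test_distinct_families_identity(self):
        df = pd.DataFrame([
            enr_row("c", "miR-1", "miRNA", 0.004),
            enr_row("c", "miR-2", "miRNA", 0.002),
            enr_row("c", "TF1", "TF", 0.003)])
        out = network.collapse_families(df)
        assert sorted(out["regulator"]) == ["TF1", "miR-1", "miR-2"]

    def test_tie_broken_lexicographically(self):
        df = pd.DataFrame([
            enr_row("c", "miR-b", "miRNA", 0.005, family="fam"),
            enr_row("c", "miR-a", "miRNA", 0.005, family="fam")])
        out = network.collapse_families(df)
        assert list(out["regulator"]) == ["miR-a"]

    def test_family_never_fully_removed(self):
        df = pd.DataFrame([
            enr_row("c1", "miR-x", "miRNA", 0.004, family="f1"),
            enr_row("c1", "miR-y", "miRNA", 0.001, family="f1"),
            enr_row("c1", "miR-z", "miRNA", 0.003, family="f2")])
        out = network.collapse_families(df)
        assert set(out["family"]) == {"f1", "f2"}

    def test_same_family_different_clusters_kept_per_cluster(self):
        df = pd.DataFrame([
            enr_row("c1", "miR-x", "miRNA", 0.004, family="f"),
            enr_row("c2", "miR-y", "miRNA", 0.002, family="f")])
        out = network.collapse_families(df)
        assert len(out) == 2


class TestBuildNetwork:
    def _collection(self):
        return GeneSetCollection([
            GeneSet("miR-1", "miRNA", ("gA", "gB", "gX")),
            GeneSet("TF1", "TF", ("gB", "gC")),
            GeneSet("TF2", "TF", ("gZ",))])

    def test_tf_only_network(self):
        enr = pd.DataFrame([enr_row("c", "TF1", "TF", 0.001)])
        net = network.build_network("c", ["gA", "gB", "gC"], enr,
                                    self._collection())
        types = {d["node_type"] for _, d in net.graph.nodes(data=True)}
        assert types == {"TF", "gene"}
        assert net.summary()["n_tf_target_edges"] == 2

    def test_empty_enrichment_empty_network(self):
        net = network.build_network("c", ["gA"], pd.DataFrame(
            columns=["cluster", "regulator", "kind", "p"]),
            self._collection())
        assert net.graph.number_of_nodes() == 0
        assert net.summary()["n_components"] == 0

    def test_regulator_without_in_cluster_targets_dropped(self, caplog):
        enr = pd.DataFrame([enr_row("c", "TF2", "TF", 0.001)])
        with caplog.at_level("WARNING"):
            net = network.build_network("c", ["gA", "gB"], enr,
                                        self._collection())
        assert "TF2" not in net.graph
        assert "no in-cluster targets" in caplog.text

    def test_degree_equals_in_cluster_target_count(self):
        enr = pd.DataFrame([enr_row("c", "miR-1", "miRNA", 0.001)])
        cluster = ["gA", "gB", "gC"]  # gX outside the cluster
        net = network.build_network("c", cluster, enr, self._collection())
        assert net.graph.out_degree("miR-1") == 2

    def test_ppi_restricted_to_cluster(self):
        enr = pd.DataFrame([enr_row("c", "TF1", "TF", 0.001)])
        ppi = [("gB", "gC"), ("gB", "gOUT")]
        net = network.build_network("c", ["gA", "gB", "gC"], enr,
                                    self._collection(), ppi)
        assert net.summary()["n_ppi_edges"] == 1
        assert "gOUT" not in net.graph

    def test_ppi_expansion_pulls_first_neighbors(self):
        enr = pd.DataFrame([enr_row("c", "TF1", "TF", 0.001)])
        ppi = [("gB", "gOUT")]
        net = network.build_network("c", ["gA", "gB", "gC"], enr,
                                    self._collection(), ppi,
                                    expand_ppi_neighbors=True)
        assert "gOUT" in net.graph
        assert net.graph.nodes["gOUT"]["node_type"] == "gene"

    def test_removing_ppi_changes_only_ppi_parts(self):
        enr = pd.DataFrame([enr_row("c", "TF1", "TF", 0.001)])
        with_ppi = network.build_network("c", ["gB", "gC", "gD", "gE"],
                                         enr, self._collection(),
                                         [("gD", "gE")])
        without = network.build_network("c", ["gB", "gC", "gD", "gE"],
                                        enr, self._collection())
        diff_nodes = set(with_ppi.graph) - set(without.graph)
        assert diff_nodes == {"gD", "gE"}  # PPI-only gene nodes
        assert [e for e in edge_multiset(with_ppi)
                if e[1] != "ppi"] == edge_multiset(without)

    def test_family_invariant_enforced_on_validate(self):
        net = network.RegulatoryNetwork("c")
        g = net.graph
        g.add_node("miR-a", node_type="miRNA", family="f")
        g.add_node("miR-b", node_type="miRNA", family="f")
        g.add_node("gA", node_type="gene")
        g.add_edge("miR-a", "gA", edge_type="mirna_target")
        g.add_edge("miR-b", "gA", edge_type="mirna_target")
        with pytest.raises(ValueError, match="family"):
            net.validate()

    def test_type_constraints_enforced(self):
        net = network.RegulatoryNetwork("c")
        g = net.graph
        g.add_node("TF1", node_type="TF")
        g.add_node("gA", node_type="gene")
        g.add_edge("gA", "TF1", edge_type="ppi")
        with pytest.raises(ValueError, match="ppi"):
            net.validate()


class TestSummary:
    def test_star_counts(self):
        net = network.RegulatoryNetwork("c")
        g = net.graph
        g.add_node("TF1", node_type="TF")
        for i in range(4):
            g.add_node(f"g{i}", node_type="gene")
            g.add_edge("TF1", f"g{i}", edge_type="tf_target")
        s = net.summary()
        assert s["n_tf_nodes"] == 1 and s["n_gene_nodes"] == 4
        assert s["n_tf_target_edges"] == 4 and s["n_components"] == 1

    def test_matches_brute_force_tally(self):
        enr = pd.DataFrame([enr_row("c", "TF1", "TF", 0.01),
                            enr_row("c", "miR-1", "miRNA", 0.002)])
        coll = GeneSetCollection([
            GeneSet("miR-1", "miRNA", ("gA", "gB")),
            GeneSet("TF1", "TF", ("gB", "gC"))])
        net = network.build_network("c", ["gA", "gB", "gC"], enr, coll,
                                    [("gA", "gC")])
        s = net.summary()
        nodes = list(net.graph.nodes(data=True))
        edges = list(net.graph.edges(data=True))
        assert s["n_gene_nodes"] == sum(
            1 for _, d in nodes if d["node_type"] == "gene")
        assert s["n_edges"] == len(edges)
        assert s["n_ppi_edges"] == sum(
            1 for *_, d in edges if d["edge_type"] == "ppi")


class TestExport:
    def _net(self):
        enr = pd.DataFrame([enr_row("c", "TF1", "TF", 0.01),
                            enr_row("c", "miR-1", "miRNA", 0.002)])
        coll = GeneSetCollection([
            GeneSet("miR-1", "miRNA", ("gA", "gB")),
            GeneSet("TF1", "TF", ("gB", "gC"))])
        return network.build_network("c", ["gA", "gB", "gC"], enr, coll,
                                     [("gA", "gC")])

    def test_two_node_network_single_sif_line(self, tmp_path):
        net = network.RegulatoryNetwork("c")
        net.graph.add_node("TF1", node_type="TF")
        net.graph.add_node("gA", node_type="gene")
        net.graph.add_edge("TF1", "gA", edge_type="tf_target")
        path = tmp_path / "n.sif"
        network.export_network(net, path, "SIF")
        assert path.read_text() == "TF1\ttf_target\tgA\n"

    def test_sif_roundtrip_preserves_multisets(self, tmp_path):
        net = self._net()
        path = tmp_path / "n.sif"
        network.export_network(net, path, "SIF")
        back = network.read_network_sif(path, "c")
        back.validate()
        assert edge_multiset(back) == edge_multiset(net)
        assert dict(back.graph.nodes(data="node_type")) == \
            dict(net.graph.nodes(data="node_type"))

    def test_graphml_roundtrip_isomorphic(self, tmp_path):
        net = self._net()
        path = tmp_path / "n.graphml"
        network.export_network(net, path, "GraphML")
        back = network.read_network_graphml(path)
        back.validate()
        assert back.cluster_id == "c"
        assert nx.is_isomorphic(
            net.graph, back.graph,
            node_match=lambda a, b: a["node_type"] == b["node_type"],
            edge_match=lambda a, b: a["edge_type"] == b["edge_type"])

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown"):
            network.export_network(self._net(), tmp_path / "x", "XGMML")

    @given(st.data())
    def test_fuzzed_roundtrip(self, tmp_path_factory, data):
        # random small typed networks, incl. node IDs with spaces
        tmp = tmp_path_factory.mktemp("fuzz")
        name_st = st.text(
            alphabet="abc XYZ_-.", min_size=1, max_size=8).map(str.strip) \
            .filter(bool)
        genes = data.draw(st.lists(name_st, min_size=1, max_size=5,
                                   unique=True))
        regs = data.draw(st.lists(name_st.map(lambda s: "R_" + s),
                                  min_size=1, max_size=3, unique=True))
        genes = [g for g in genes if g not in regs]
        if not genes:
            return
        net = network.RegulatoryNetwork("fuzz")
        g = net.graph
        for gene in genes:
            g.add_node(gene, node_type="gene")
        for i, r in enumerate(regs):
            kind = "miRNA" if i % 2 else "TF"
            g.add_node(r, node_type=kind)
            target = genes[i % len(genes)]
            g.add_edge(r, target,
                       edge_type=network._TARGET_EDGE_OF[kind])
        if len(genes) >= 2:
            a, b = sorted(genes[:2])
            g.add_edge(a, b, edge_type="ppi")
        net.validate()
        for fmt, reader in (("SIF", network.read_network_sif),
                            ("GraphML", network.read_network_graphml)):
            path = tmp / f"fuzz.{fmt.lower()}"
            network.export_network(net, path, fmt)
            back = reader(path)
            assert edge_multiset(back) == edge_multiset(net)
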