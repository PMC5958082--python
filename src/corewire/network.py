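"""Per-cluster miRNA + TF co-regulatory network assembly and export.

A cluster's network joins its enriched regulators (miRNAs and TFs, at most
one miRNA per functional family) to their target genes inside the cluster,
plus protein-protein interaction edges between cluster genes.  Nodes are
typed (``gene``, ``miRNA``, ``TF``); edges are typed (``mirna_target``,
``tf_target``, ``ppi``).  Regulator-target edges run regulator -> gene;
PPI edges are undirected and stored once with endpoints in lexicographic
order.  Networks are exported as SIF or GraphML for Cytoscape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Collection, Iterable, Sequence

import networkx as nx
import pandas as pd

from .io import GeneSetCollection

logger = logging.getLogger(__name__)

NODE_TYPES = ("gene", "miRNA", "TF")
EDGE_TYPES = ("mirna_target", "tf_target", "ppi")
_TARGET_EDGE_OF = {"miRNA": "mirna_target", "TF": "tf_target"}


@dataclass
class RegulatoryNetwork:
    """A typed tripartite regulatory graph for one cluster.

    ``graph`` is a directed networkx graph; node attribute ``node_type``
    and edge attribute ``edge_type`` carry the typing, regulator nodes
    additionally carry their enrichment ``p_value``.
    """

    cluster_id: str
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def validate(self) -> None:
        """Enforce the structural contract (typing, no self-loops, every
        regulator keeps at least one target edge, one miRNA per family)."""
        g = self.graph
        for node, data in g.nodes(data=True):
            if data.get("node_type") not in NODE_TYPES:
                raise ValueError(f"node {node!r} has invalid type "
                                 f"{data.get('node_type')!r}")
        families: dict[str, str] = {}
        for node, data in g.nodes(data=True):
            if data.get("node_type") == "miRNA":
                fam = data.get("family") or node
                if fam in families:
                    raise ValueError(
                        f"two miRNAs from family {fam!r}: "
                        f"{families[fam]!r} and {node!r}")
                families[fam] = node
        for u, v, data in g.edges(data=True):
            et = data.get("edge_type")
            if et not in EDGE_TYPES:
                raise ValueError(f"edge {u!r}->{v!r} has invalid type "
                                 f"{et!r}")
            if u == v:
                raise ValueError(f"self-loop at {u!r}")
            tu = g.nodes[u]["node_type"]
            tv = g.nodes[v]["node_type"]
            if et == "ppi":
                if tu != "gene" or tv != "gene":
                    raise ValueError(f"ppi edge on non-gene nodes "
                                     f"{u!r}, {v!r}")
            else:
                if tv != "gene" or _TARGET_EDGE_OF.get(tu) != et:
                    raise ValueError(
                        f"{et} edge must run {et.split('_')[0]} "
                        f"regulator -> gene ({u!r} -> {v!r})")
        for node, data in g.nodes(data=True):
            if data["node_type"] in ("miRNA", "TF"):
                has_target = any(
                    d["edge_type"] in ("mirna_target", "tf_target")
                    for _, _, d in g.out_edges(node, data=True))
                if not has_target:
                    raise ValueError(f"regulator {node!r} has no target "
                                     "edge")

    def summary(self) -> dict[str, int]:
        """Node counts by type, edge counts by type, and weakly connected
        component count."""
        g = self.graph
        out = {f"n_{t}_nodes".replace("miRNA", "mirna").replace("TF", "tf"):
               sum(1 for _, d in g.nodes(data=True) if d["node_type"] == t)
               for t in NODE_TYPES}
        for et in EDGE_TYPES:
            out[f"n_{et}_edges"] = sum(
                1 for _, _, d in g.edges(data=True) if d["edge_type"] == et)
        out["n_nodes"] = g.number_of_nodes()
        out["n_edges"] = g.number_of_edges()
        out["n_components"] = (
            nx.number_weakly_connected_components(g) if len(g) else 0)
        return out


def collapse_families(enrichment: pd.DataFrame) -> pd.DataFrame:
    """Keep one miRNA per functional family: the member with the smallest
    enrichment p (ties broken lexicographically by name).

    Operates per cluster on an :func:`~corewire.enrichment.enrich_all`-style
    table; TF rows and miRNAs without a family pass through unchanged
    (a missing family means the miRNA is its own family).
    """
    if enrichment.empty:
        return enrichment.copy()
    df = enrichment.copy()
    fam = df["family"].where(df["family"].notna(), df["regulator"])
    is_mirna = df["kind"] == "miRNA"
    keep_idx = []
    grouped = df[is_mirna].assign(_fam=fam[is_mirna]).groupby(
        ["cluster", "_fam"], sort=False)
    for _, sub in grouped:
        best = sub.sort_values(["p", "regulator"], kind="stable").index[0]
        keep_idx.append(best)
    kept = df.loc[sorted(set(keep_idx) | set(df.index[~is_mirna]))]
    return kept.sort_values(["cluster", "p", "regulator"],
                            kind="stable").reset_index(drop=True)


def build_network(cluster_id: str, cluster_genes: Collection[str],
                  enriched_regulators: pd.DataFrame,
                  collections: GeneSetCollection,
                  ppi: Sequence[tuple[str, str]] = (),
                  expand_ppi_neighbors: bool = False) -> RegulatoryNetwork:
    """Assemble one cluster's co-regulatory network.

    ``enriched_regulators`` is the (family-collapsed) significant subset of
    the enrichment table, already filtered to this cluster or carrying a
    ``cluster`` column to filter on.  Gene nodes are cluster genes reached
    by at least one regulator edge or PPI edge; regulators with no
    in-cluster targets are dropped with a warning.  PPI edges are kept when
    both endpoints are cluster genes (with ``expand_ppi_neighbors``, when
    at least one endpoint is an already-included gene node).
    """
    cluster = set(cluster_genes)
    net = RegulatoryNetwork(cluster_id=cluster_id)
    g = net.graph

    regs = enriched_regulators
    if "cluster" in regs.columns:
        regs = regs[regs["cluster"] == cluster_id]
    for _, row in regs.iterrows():
        name = row["regulator"]
        try:
            gene_set = collections[name]
        except KeyError:
            raise KeyError(f"enriched regulator {name!r} not in the "
                           "gene-set collection") from None
        targets = sorted(set(gene_set.members) & cluster)
        if not targets:
            logger.warning("regulator %s has no in-cluster targets; "
                           "dropped from %s network", name, cluster_id)
            continue
        g.add_node(name, node_type=row["kind"],
                   family=gene_set.family or "",
                   p_value=float(row["p"]))
        for t in targets:
            g.add_node(t, node_type="gene")
            g.add_edge(name, t, edge_type=_TARGET_EDGE_OF[row["kind"]])

    gene_nodes = {n for n, d in g.nodes(data=True)
                  if d["node_type"] == "gene"}
    for a, b in ppi:
        a, b = sorted((a, b))
        if a == b:
            continue
        if expand_ppi_neighbors:
            # first-neighbor expansion: pull in outside interactors of
            # genes already present in the network
            keep = a in gene_nodes or b in gene_nodes
        else:
            keep = a in cluster and b in cluster
        if keep:
            for node in (a, b):
                if node not in g:
                    g.add_node(node, node_type="gene")
            g.add_edge(a, b, edge_type="ppi")

    net.validate()
    return net


def network_summary(network: RegulatoryNetwork) -> dict[str, int]:
    return network.summary()


# ---------------------------------------------------------------------------
# export / import

def export_network(network: RegulatoryNetwork, path: str | Path,
                   format: str = "SIF") -> None:
    """Write the network as SIF (``source TAB edge_type TAB target``) or
    GraphML with node_type/edge_type attributes."""
    path = Path(path)
    fmt = format.upper()
    if fmt == "SIF":
        with open(path, "w") as fh:
            for u, v, data in sorted(network.graph.edges(data=True)):
                fh.write(f"{u}\t{data['edge_type']}\t{v}\n")
    elif fmt == "GRAPHML":
        g = network.graph.copy()
        g.graph["cluster_id"] = network.cluster_id
        nx.write_graphml(g, path, named_key_ids=True)
    else:
        raise ValueError(f"unknown network format {format!r} "
                         "(use SIF or GraphML)")


def read_network_sif(path: str | Path, cluster_id: str = "") -> \
        RegulatoryNetwork:
    """Parse a SIF file written by :func:`export_network`.

    Node types are inferred from edge types, which is lossless for valid
    networks (every regulator has a typed target edge; all other nodes are
    genes).
    """
    net = RegulatoryNetwork(cluster_id=cluster_id)
    g = net.graph
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: SIF line needs 3 "
                                 "tab-separated fields")
            u, et, v = fields
            if et not in EDGE_TYPES:
                raise ValueError(f"{path}:{lineno}: unknown edge type "
                                 f"{et!r}")
            src_type = {"mirna_target": "miRNA", "tf_target": "TF",
                        "ppi": "gene"}[et]
            if u not in g or g.nodes[u].get("node_type") == "gene":
                g.add_node(u, node_type=src_type)
            g.add_node(v, node_type=g.nodes[v]["node_type"]
                       if v in g else "gene")
            g.add_edge(u, v, edge_type=et)
    return net


def read_network_graphml(path: str | Path) -> RegulatoryNetwork:
    g = nx.read_graphml(path)
    if not g.is_directed():
        g = g.to_directed()
    net = RegulatoryNetwork(cluster_id=g.graph.get("cluster_id", ""),
                            graph=nx.DiGraph(g))
    return net
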