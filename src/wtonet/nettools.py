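"""Post-processing of wTO / consensus edge lists.

Filtering by |weight| and p-value, community detection on |weight| (the
sign is kept as a link attribute — modularity-style algorithms need
nonnegative weights), and export to interoperable formats (edge TSV and
GraphML, which Cytoscape reads directly).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["WeightedGraph", "filter_links", "cluster_nodes", "export_graph",
           "read_graphml", "CLUSTER_METHODS"]

CLUSTER_METHODS = ("walktrap", "optimal", "spinglass", "edge_betweenness",
                   "fast_greedy", "infomap", "louvain", "label_prop",
                   "leading_eigen")


@dataclass
class WeightedGraph:
    """Undirected links with signed weight and p-value.

    ``node_classes`` labels nodes by kind (e.g. TF vs target);
    ``clusters`` holds a community id per node once assigned.
    """

    edges: pd.DataFrame                          # Node.1, Node.2, weight, pval
    node_classes: dict[str, str] = field(default_factory=dict)
    clusters: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        df = self.edges.copy()
        df.columns = ["Node.1", "Node.2", "weight", "pval"]
        a = df["Node.1"].astype(str)
        b = df["Node.2"].astype(str)
        swap = a > b
        df["Node.1"] = a.where(~swap, b)
        df["Node.2"] = b.where(~swap, a)
        if (df["Node.1"] == df["Node.2"]).any():
            raise ValueError("self-loops are not allowed")
        if df.duplicated(subset=["Node.1", "Node.2"]).any():
            raise ValueError("duplicate unordered pairs")
        self.edges = df.reset_index(drop=True)

    @property
    def nodes(self) -> list[str]:
        return sorted(set(self.edges["Node.1"]) | set(self.edges["Node.2"]))

    def degree(self) -> pd.Series:
        """Count of retained links per node."""
        return pd.concat([self.edges["Node.1"], self.edges["Node.2"]]) \
                 .value_counts().sort_index()

    def strength(self) -> pd.Series:
        """Sum of |weight| over a node's links."""
        s = pd.concat([
            self.edges.set_index("Node.1")["weight"].abs(),
            self.edges.set_index("Node.2")["weight"].abs(),
        ])
        return s.groupby(level=0).sum().sort_index()

    @classmethod
    def from_significance_table(cls, table: pd.DataFrame,
                                weight_col: str = "wTO_sign",
                                pval_col: str = "padj_sig",
                                **kw) -> "WeightedGraph":
        cols = table[["Node.1", "Node.2", weight_col, pval_col]]
        return cls(cols, **kw)


def filter_links(g: WeightedGraph, min_abs_weight: float = 0.0,
                 max_p: float = 1.0) -> WeightedGraph:
    """Keep links with |weight| >= min_abs_weight and p <= max_p (ties kept)."""
    if min_abs_weight < 0 or not 0 <= max_p <= 1:
        raise ValueError("thresholds out of range")
    keep = (g.edges["weight"].abs() >= min_abs_weight) & (g.edges["pval"] <= max_p)
    kept = g.edges.loc[keep].reset_index(drop=True)
    return WeightedGraph(kept, dict(g.node_classes), dict(g.clusters))


def _to_igraph(g: WeightedGraph) -> ig.Graph:
    nodes = g.nodes
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in
             zip(g.edges["Node.1"], g.edges["Node.2"])]
    graph = ig.Graph(n=len(nodes), edges=edges)
    graph.vs["name"] = nodes
    graph.es["weight"] = g.edges["weight"].abs().tolist()
    return graph


def _per_component(graph: ig.Graph, fn) -> ig.VertexClustering:
    membership = [0] * graph.vcount()
    offset = 0
    for comp in graph.connected_components():
        sub = graph.subgraph(comp)
        sub_part = fn(sub)
        for v, c in zip(comp, sub_part.membership):
            membership[v] = c + offset
        offset += max(sub_part.membership, default=-1) + 1
    return ig.VertexClustering(graph, membership)


def cluster_nodes(g: WeightedGraph, method: str = "louvain",
                  seed: int = 0) -> dict[str, int]:
    """Community detection on |weight|; cluster ids contiguous from 0.

    Stochastic methods are made deterministic by seeding the igraph RNG.
    """
    if method not in CLUSTER_METHODS:
        raise ValueError(f"unknown clustering method {method!r}; "
                         f"choose one of {CLUSTER_METHODS}")
    graph = _to_igraph(g)
    if graph.vcount() == 0:
        return {}
    ig.set_random_number_generator(random.Random(seed))
    w = "weight"
    if method == "walktrap":
        part = graph.community_walktrap(weights=w).as_clustering()
    elif method == "optimal":
        part = graph.community_optimal_modularity(weights=w)
    elif method == "spinglass":
        # spinglass and the edge-betweenness dendrogram need connected
        # graphs; decompose and stitch memberships back together
        part = _per_component(graph, lambda sub: sub.community_spinglass(weights=w))
    elif method == "edge_betweenness":
        part = _per_component(
            graph,
            lambda sub: sub.community_edge_betweenness(weights=w).as_clustering())
    elif method == "fast_greedy":
        part = graph.community_fastgreedy(weights=w).as_clustering()
    elif method == "infomap":
        part = graph.community_infomap(edge_weights=w)
    elif method == "louvain":
        part = graph.community_multilevel(weights=w)
    elif method == "label_prop":
        part = graph.community_label_propagation(weights=w)
    else:  # leading_eigen
        part = graph.community_leading_eigenvector(weights=w)
    membership = part.membership
    # relabel to contiguous ids in first-appearance order
    relabel: dict[int, int] = {}
    out: dict[str, int] = {}
    for name, c in zip(graph.vs["name"], membership):
        if c not in relabel:
            relabel[c] = len(relabel)
        out[name] = relabel[c]
    g.clusters = out
    return out


def export_graph(g: WeightedGraph, path: str,
                 fmt: str = "edge_tsv") -> None:
    """Write the graph as an edge TSV or attribute-rich GraphML file."""
    if fmt == "edge_tsv":
        g.edges.to_csv(path, sep="\t", index=False, float_format="%.12g")
    elif fmt == "graphml":
        nxg = nx.Graph()
        for n in g.nodes:
            nxg.add_node(n,
                         node_class=g.node_classes.get(n, ""),
                         cluster=int(g.clusters.get(n, -1)))
        for row in g.edges.itertuples(index=False):
            nxg.add_edge(row[0], row[1],
                         weight=float(row.weight),
                         sign=int(np.sign(row.weight)),
                         pval=float(row.pval))
        nx.write_graphml(nxg, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}; "
                         "choose 'edge_tsv' or 'graphml'")


def read_graphml(path: str) -> WeightedGraph:
    """Read back a GraphML file written by export_graph (round-trip)."""
    nxg = nx.read_graphml(path)
    rows = [(a, b, d["weight"], d["pval"]) for a, b, d in nxg.edges(data=True)]
    edges = pd.DataFrame(rows, columns=["Node.1", "Node.2", "weight", "pval"])
    classes = {n: d.get("node_class", "") for n, d in nxg.nodes(data=True)
               if d.get("node_class")}
    clusters = {n: int(d["cluster"]) for n, d in nxg.nodes(data=True)
                if int(d.get("cluster", -1)) >= 0}
    return WeightedGraph(edges, classes, clusters)
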