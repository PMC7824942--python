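"""Sample-organized TCR sharing network and diagnosis-group sharing counts.

The network has two node levels: one hub per sample and one leaf per
clonal clonotype, each leaf attached to its sample's hub.  Leaf-leaf
similarity edges connect clonotype pairs whose L-sim exceeds tau.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from tcrsimnet.similarity import SimilarityMatrix


class IntegrityError(ValueError):
    pass


@dataclass
class TCRNetwork:
    graph: nx.Graph
    tau: float

    @property
    def hub_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "hub"]

    @property
    def leaf_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "leaf"]

    @property
    def similarity_edges(self) -> list[tuple[str, str, dict]]:
        return [
            (u, v, d)
            for u, v, d in self.graph.edges(data=True)
            if d.get("kind") == "similarity"
        ]

    @property
    def attachment_edges(self) -> list[tuple[str, str, dict]]:
        return [
            (u, v, d)
            for u, v, d in self.graph.edges(data=True)
            if d.get("kind") == "attachment"
        ]


def build_network(
    clonotypes,
    matrix: SimilarityMatrix,
    tau: float,
    group_by_sample: dict[str, str] | None = None,
) -> TCRNetwork:
    """Build the hub/leaf sharing network at threshold tau.

    Hubs are created for every sample contributing a clonotype; every
    clonotype becomes a leaf attached to its sample hub, retained even
    when it has no similarity edge.  Similarity edges are added for all
    pairs with score strictly above tau.
    """
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must be in (0, 1)")
    covered = set(matrix.clonotype_order)
    for ct in clonotypes:
        if ct.clonotype_id not in covered:
            raise IntegrityError(f"clonotype {ct.clonotype_id} missing from similarity matrix")
    group_by_sample = group_by_sample or {}
    g = nx.Graph()
    by_id = {}
    for ct in clonotypes:
        by_id[ct.clonotype_id] = ct
        sample = ct.sample_id or ";".join(sorted(ct.samples))
        group = group_by_sample.get(sample, ";".join(sorted(ct.groups)))
        hub = f"sample:{sample}"
        if hub not in g:
            g.add_node(hub, kind="hub", sample_id=sample, group=group)
        leaf = f"tcr:{ct.clonotype_id}"
        g.add_node(
            leaf,
            kind="leaf",
            sample_id=sample,
            group=group,
            cdr3a=ct.cdr3a or "",
            cdr3b=ct.cdr3b,
            size=ct.size,
        )
        g.add_edge(hub, leaf, kind="attachment")
    wanted = set(by_id)
    for id_i, id_j, score in matrix.iter_pairs():
        if id_i in wanted and id_j in wanted and score > tau:
            g.add_edge(f"tcr:{id_i}", f"tcr:{id_j}", kind="similarity", lsim=float(score))
    return TCRNetwork(graph=g, tau=tau)


def group_sharing_counts(
    network: TCRNetwork, include_within_sample: bool = False
) -> pd.DataFrame:
    """Symmetric matrix counting similarity edges per diagnosis-group pair.

    Each edge increments the cell for its unordered group pair; within-
    group edges land on the diagonal.  Edges between clonotypes of the
    same sample are excluded by default (sharing between unique samples).
    """
    g = network.graph
    groups = sorted({d.get("group", "") for _, d in g.nodes(data=True) if d.get("kind") == "leaf"})
    counts = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    for u, v, d in network.similarity_edges:
        su, sv = g.nodes[u]["sample_id"], g.nodes[v]["sample_id"]
        if su == sv and not include_within_sample:
            continue
        gu, gv = g.nodes[u]["group"], g.nodes[v]["group"]
        a, b = sorted((gu, gv))
        counts.loc[a, b] += 1
        if a != b:
            counts.loc[b, a] += 1
    return counts


def export_network(network: TCRNetwork, path: str | Path, format: str = "graphml") -> list[Path]:
    """Write the network as GraphML or as node/edge CSVs.

    ``edge_csv`` writes ``<path>.nodes.csv`` and ``<path>.edges.csv``.
    Both formats round-trip through :func:`import_network`.
    """
    path = Path(path)
    if format == "graphml":
        g = network.graph.copy()
        g.graph["tau"] = network.tau
        nx.write_graphml(g, path)
        return [path]
    if format == "edge_csv":
        nodes_path = path.with_suffix(path.suffix + ".nodes.csv")
        edges_path = path.with_suffix(path.suffix + ".edges.csv")
        node_rows = [{"node": n, **d} for n, d in network.graph.nodes(data=True)]
        edge_rows = [{"source": u, "target": v, **d} for u, v, d in network.graph.edges(data=True)]
        node_cols = ["node", "kind", "sample_id", "group", "cdr3a", "cdr3b", "size"]
        edge_cols = ["source", "target", "kind", "lsim"]
        pd.DataFrame(node_rows).reindex(columns=node_cols).to_csv(nodes_path, index=False)
        pd.DataFrame(edge_rows).reindex(columns=edge_cols).to_csv(edges_path, index=False)
        return [nodes_path, edges_path]
    raise ValueError(f"unknown export format {format!r}")


def import_network(path: str | Path, format: str = "graphml") -> TCRNetwork:
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        tau = float(g.graph.get("tau", 0.0))
        return TCRNetwork(graph=nx.Graph(g), tau=tau)
    if format == "edge_csv":
        nodes = pd.read_csv(path.with_suffix(path.suffix + ".nodes.csv"), keep_default_na=False)
        edges = pd.read_csv(path.with_suffix(path.suffix + ".edges.csv"), keep_default_na=False)
        g = nx.Graph()
        for row in nodes.to_dict(orient="records"):
            node = row.pop("node")
            g.add_node(node, **{k: v for k, v in row.items() if v != ""})
        for row in edges.to_dict(orient="records"):
            u, v = row.pop("source"), row.pop("target")
            g.add_edge(u, v, **{k: v for k, v in row.items() if v != ""})
        return TCRNetwork(graph=g, tau=0.0)
    raise ValueError(f"unknown import format {format!r}")


def plot_network(network: TCRNetwork, path: str | Path, seed: int = 0) -> None:
    """Best-effort spring-layout rendering; structure, not pixels, is the contract."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = network.graph
    pos = nx.spring_layout(g, seed=seed)
    hubs = [n for n, d in g.nodes(data=True) if d.get("kind") == "hub"]
    leaves = [n for n, d in g.nodes(data=True) if d.get("kind") == "leaf"]
    fig, ax = plt.subplots(figsize=(8, 8))
    nx.draw_networkx_nodes(g, pos, nodelist=hubs, node_size=300, node_color="tab:blue", ax=ax)
    nx.draw_networkx_nodes(g, pos, nodelist=leaves, node_size=30, node_color="tab:gray", ax=ax)
    attach = [(u, v) for u, v, d in g.edges(data=True) if d.get("kind") == "attachment"]
    sim = [(u, v) for u, v, d in g.edges(data=True) if d.get("kind") == "similarity"]
    nx.draw_networkx_edges(g, pos, edgelist=attach, edge_color="lightgray", ax=ax)
    nx.draw_networkx_edges(g, pos, edgelist=sim, edge_color="tab:red", ax=ax)
    ax.set_axis_off()
    fig.savefig(path, dpi=150)
    plt.close(fig)
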