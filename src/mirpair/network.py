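"""Directed bipartite miRNA -> mRNA regulatory network analysis.

A filtered pair set becomes a directed graph with one typed node per feature
(kind mirna/mrna, direction up/down from the DE tables) and one edge per
pair, always miRNA -> mRNA. Because negative pairs couple an up-regulator to
a down-target (and vice versa), the graph separates into an up-miRNA and a
down-miRNA subnetwork; a warning fires if an edge violates that expectation.

Node metrics are outdegree and out-closeness, where closeness is the number
of out-reachable nodes divided by the sum of shortest-path distances to them
(0 when nothing is reachable). In a pure bipartite graph every regulator's
reachable set sits at distance 1, so every connected miRNA has closeness
exactly 1 and hub calling reduces to the outdegree cut (strict >, default
25) at closeness >= 1.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .pair_inference import PairSet

logger = logging.getLogger("mirpair")


def build_network(
    pair_set: PairSet, de_mirna: pd.DataFrame, de_mrna: pd.DataFrame
) -> nx.DiGraph:
    """One node per distinct feature, one miRNA->mRNA edge per pair."""
    dir_mi = de_mirna.set_index("feature_id")["direction"]
    dir_mr = de_mrna.set_index("feature_id")["direction"]
    graph = nx.DiGraph()
    leaks = 0
    for mi, mr in zip(pair_set.records["mirna_id"], pair_set.records["mrna_id"]):
        if mi not in dir_mi.index:
            raise ValueError(f"pair references unknown miRNA {mi!r}")
        if mr not in dir_mr.index:
            raise ValueError(f"pair references unknown mRNA {mr!r}")
        graph.add_node(mi, kind="mirna", direction=dir_mi[mi])
        graph.add_node(mr, kind="mrna", direction=dir_mr[mr])
        graph.add_edge(mi, mr)
        if dir_mi[mi] == dir_mr[mr]:
            leaks += 1
    if leaks:
        logger.warning(
            "%d edge(s) join same-direction nodes; a positive-correlation pair may have leaked through",
            leaks,
        )
    logger.info("network: %d nodes, %d edges", graph.number_of_nodes(), graph.number_of_edges())
    return graph


def node_metrics(graph: nx.DiGraph) -> pd.DataFrame:
    """Outdegree and out-closeness per node.

    closeness = (#out-reachable nodes) / (sum of shortest-path distances to
    them); 0 with no outgoing edges, exactly 1 when everything reachable is a
    direct target.
    """
    rows = []
    for node in graph.nodes:
        lengths = nx.single_source_shortest_path_length(graph, node)
        lengths.pop(node, None)
        total = sum(lengths.values())
        closeness = len(lengths) / total if total else 0.0
        rows.append(
            {
                "node": node,
                "kind": graph.nodes[node].get("kind", ""),
                "direction": graph.nodes[node].get("direction", ""),
                "outdegree": graph.out_degree(node),
                "closeness": closeness,
            }
        )
    return pd.DataFrame(rows).sort_values("node", kind="mergesort", ignore_index=True)


def hub_report(
    graph: nx.DiGraph, min_closeness: float = 1.0, min_outdegree: int = 25
) -> pd.DataFrame:
    """Regulator hubs: closeness >= min_closeness and outdegree strictly > cut.

    Ranked by outdegree descending, ties lexicographic.
    """
    metrics = node_metrics(graph)
    hubs = metrics[
        (metrics["closeness"] >= min_closeness) & (metrics["outdegree"] > min_outdegree)
    ]
    return hubs.sort_values(
        by=["outdegree", "node"], ascending=[False, True], kind="mergesort", ignore_index=True
    )


def export_network(graph: nx.DiGraph, path: str | Path, format: str = "sif") -> None:
    """Write the graph for Cytoscape: SIF edges or GraphML with attributes."""
    path = Path(path)
    if format == "sif":
        with open(path, "w") as fh:
            for mi, mr in sorted(graph.edges):
                fh.write(f"{mi}\ttargets\t{mr}\n")
    elif format == "graphml":
        export = graph.copy()
        metrics = node_metrics(graph).set_index("node")
        for node in export.nodes:
            export.nodes[node]["outdegree"] = int(metrics.loc[node, "outdegree"])
            export.nodes[node]["closeness"] = float(metrics.loc[node, "closeness"])
        nx.write_graphml(export, path)
    else:
        raise ValueError(f"unknown export format {format!r}; expected 'sif' or 'graphml'")


def import_network(path: str | Path, format: str = "sif") -> nx.DiGraph:
    path = Path(path)
    if format == "sif":
        graph = nx.DiGraph()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 3 or parts[1] != "targets":
                    raise ValueError(f"malformed SIF line: {line!r}")
                graph.add_edge(parts[0], parts[2])
        return graph
    if format == "graphml":
        return nx.read_graphml(path)
    raise ValueError(f"unknown import format {format!r}; expected 'sif' or 'graphml'")
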