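"""Directed movement networks between receiver stations.

Nodes are receiver locations; a directed edge ``A -> B`` counts, over all
animals, the consecutive residence-event pairs in which an animal's next
event after one at ``A`` was at ``B``. Node degree is the number of
distinct partner stations (union of in- and out-neighbours); node strength
is the total number of movements through the node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd


@dataclass
class MovementNetwork:
    graph: nx.DiGraph = field(repr=False)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edge_counts(self) -> pd.DataFrame:
        rows = [(u, v, d["count"]) for u, v, d in self.graph.edges(data=True)]
        return (
            pd.DataFrame(rows, columns=["from", "to", "count"])
            .sort_values(["from", "to"])
            .reset_index(drop=True)
        )

    def node_degree(self) -> pd.Series:
        """Distinct connected partners per node (in/out union, self excluded)."""
        deg = {}
        for node in self.graph.nodes:
            partners = set(self.graph.successors(node)) | set(self.graph.predecessors(node))
            partners.discard(node)
            deg[node] = len(partners)
        return pd.Series(deg, name="degree").sort_index()

    def node_strength(self) -> pd.Series:
        """Total movements through each node (in-count + out-count)."""
        s = {}
        for node in self.graph.nodes:
            s[node] = sum(d["count"] for _, _, d in self.graph.in_edges(node, data=True)) + sum(
                d["count"] for _, _, d in self.graph.out_edges(node, data=True)
            )
        return pd.Series(s, name="strength").sort_index()

    def total_movements(self) -> int:
        return sum(d["count"] for _, _, d in self.graph.edges(data=True))


def movement_matrix(
    events: pd.DataFrame,
    include_self_loops: bool = False,
    max_gap_h: float | None = None,
    island_of: dict[str, str] | None = None,
) -> MovementNetwork:
    """Count transitions between consecutive residence events of each tag.

    Parameters
    ----------
    events
        Residence events with ``tag_id``, ``station_id``, ``start``, ``end``.
    include_self_loops
        Count consecutive same-station pairs as self-loops (default: ignore).
    max_gap_h
        If set, transitions across a gap (next start − previous end) longer
        than this many hours are suppressed; default counts all consecutive
        pairs regardless of elapsed time.
    island_of
        Optional station -> island mapping; aggregates nodes to islands.

    Raises
    ------
    ValueError
        If one tag's events overlap in time (violates segmentation output).
    """
    g = nx.DiGraph()
    label = (lambda s: island_of[s]) if island_of else (lambda s: s)
    for station in events["station_id"].unique():
        g.add_node(label(str(station)))
    for tag, grp in events.groupby("tag_id"):
        grp = grp.sort_values("start", kind="stable")
        if (grp["start"].iloc[1:].to_numpy() < grp["end"].iloc[:-1].to_numpy()).any():
            raise ValueError(f"overlapping events for tag {tag}")
        prev_station = None
        prev_end = None
        for station, start, end in zip(grp["station_id"], grp["start"], grp["end"]):
            if prev_station is not None:
                gap_ok = (
                    max_gap_h is None
                    or (start - prev_end).total_seconds() <= max_gap_h * 3600.0
                )
                u, v = label(str(prev_station)), label(str(station))
                if gap_ok and (u != v or include_self_loops):
                    if g.has_edge(u, v):
                        g[u][v]["count"] += 1
                    else:
                        g.add_edge(u, v, count=1)
            prev_station, prev_end = station, end
    return MovementNetwork(graph=g)


def export_network(network: MovementNetwork, edge_csv_path=None, graphml_path=None) -> None:
    """Write the network as an edge-list CSV and/or GraphML with count attributes."""
    if edge_csv_path is not None:
        network.edge_counts().to_csv(edge_csv_path, index=False)
    if graphml_path is not None:
        nx.write_graphml(network.graph, graphml_path)


def read_network(graphml_path) -> MovementNetwork:
    """Read a GraphML export back; edge ``count`` attributes become ints."""
    g = nx.read_graphml(graphml_path)
    out = nx.DiGraph()
    out.add_nodes_from(g.nodes)
    for u, v, d in g.edges(data=True):
        out.add_edge(u, v, count=int(d["count"]))
    return MovementNetwork(graph=out)
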