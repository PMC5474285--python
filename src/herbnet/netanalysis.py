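"""Bipartite network construction, degree and betweenness centrality, ranking.

Networks are undirected and unweighted. Betweenness follows Brandes'
algorithm (via networkx) with endpoints excluded; normalized values divide
the raw accumulation by (N-1)(N-2)/2 where N is the order of the whole
graph, the convention used by common network viewers, applied unchanged to
disconnected graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import ValidationError


@dataclass
class BipartiteNetwork:
    """Two-partition undirected graph; isolated declared nodes are kept."""

    left_nodes: frozenset[str]
    right_nodes: frozenset[str]
    graph: nx.Graph = field(repr=False)

    def nodes(self) -> list[str]:
        return list(self.graph.nodes())

    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges())

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_bipartite(edges: list[tuple[str, str]],
                    left_ids: list[str],
                    right_ids: list[str]) -> BipartiteNetwork:
    """Build a bipartite network from (left, right) edge pairs.

    Every edge must join a declared left id to a declared right id; edges
    within one partition, self-loops and undeclared endpoints are errors.
    Duplicate edges are stored once.
    """
    left = frozenset(left_ids)
    right = frozenset(right_ids)
    if left & right:
        raise ValidationError(
            f"partitions overlap: {sorted(left & right)[:5]}")
    g = nx.Graph()
    g.add_nodes_from(sorted(left), bipartite=0)
    g.add_nodes_from(sorted(right), bipartite=1)
    for u, v in edges:
        if u == v:
            raise ValidationError(f"self-loop on {u!r}")
        if u in left and v in right:
            g.add_edge(u, v)
        elif u in right and v in left:
            g.add_edge(v, u)
        else:
            raise ValidationError(
                f"edge ({u!r}, {v!r}) does not cross the partitions")
    return BipartiteNetwork(left_nodes=left, right_nodes=right, graph=g)


def degree_centrality(network: BipartiteNetwork) -> pd.DataFrame:
    """Per-node degree (incident edge count) with partition labels."""
    rows = [(n, "left" if n in network.left_nodes else "right",
             network.graph.degree(n))
            for n in sorted(network.nodes())]
    return pd.DataFrame(rows, columns=["node_id", "partition", "degree"]
                        ).set_index("node_id")


def betweenness_centrality(network: BipartiteNetwork,
                           normalized: bool = True) -> pd.DataFrame:
    """Shortest-path betweenness per node, endpoints excluded.

    normalized=True divides by (N-1)(N-2)/2 over the whole graph; for
    N < 3 all values are 0 (no division attempted).
    """
    bc = nx.betweenness_centrality(network.graph, normalized=normalized,
                                   endpoints=False)
    rows = [(n, "left" if n in network.left_nodes else "right", bc[n])
            for n in sorted(network.nodes())]
    return pd.DataFrame(rows, columns=["node_id", "partition", "betweenness"]
                        ).set_index("node_id")


def centrality_table(network: BipartiteNetwork,
                     normalized: bool = True) -> pd.DataFrame:
    """Degree and normalized betweenness in one table."""
    deg = degree_centrality(network)
    bet = betweenness_centrality(network, normalized=normalized)
    return deg.join(bet["betweenness"])


def rank_nodes(table: pd.DataFrame, metric: str,
               partition: str | None = None) -> list[str]:
    """Node ids in descending metric order; ties broken lexicographically.

    metric is 'degree' or 'betweenness'; partition optionally restricts to
    'left' or 'right' nodes.
    """
    if metric not in ("degree", "betweenness"):
        raise ValidationError(f"unknown metric {metric!r}")
    if metric not in table.columns:
        raise ValidationError(f"table has no {metric!r} column")
    sub = table if partition is None else table[table["partition"] == partition]
    ordered = sorted(sub.index, key=lambda n: (-sub.loc[n, metric], n))
    return list(ordered)
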