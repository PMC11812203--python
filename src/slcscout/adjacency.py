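"""Metabolite conversion distances on the reaction network.

A reaction graph edge is one biochemical conversion step; the adjacency
matrix holds the minimum number of steps between every metabolite pair
(unreachable pairs are non-adjacent).  The graph is treated as
undirected: substrate-derivative proximity is symmetric.  Currency
metabolites that participate in very many reactions can be excluded via
a degree cap or an explicit exclusion list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .data_model import ValidationError

#: Distance value for metabolite pairs with no connecting path.
NON_ADJACENT = math.inf


@dataclass
class AdjacencyMatrix:
    """Pairwise minimum conversion-step distances between metabolites."""

    distances: pd.DataFrame  # symmetric, inf = non-adjacent
    removed_nodes: list[str] = field(default_factory=list)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.distances.index)

    def distance(self, a: str, b: str) -> float:
        if a not in self.distances.index or b not in self.distances.index:
            raise KeyError(f"unknown metabolite in distance query: {a!r} / {b!r}")
        return float(self.distances.at[a, b])

    def __contains__(self, met: str) -> bool:
        return met in self.distances.index


def conversion_distances(
    graph: nx.Graph,
    max_degree: int | None = None,
    exclude: list[str] | None = None,
) -> AdjacencyMatrix:
    """All-pairs shortest-path conversion distances.

    ``max_degree`` removes hub nodes (degree above the cap) before the
    distance computation; ``exclude`` removes named nodes (the manual
    currency-metabolite list).  Removed nodes are recorded and absent
    from the output.
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("conversion_distances: empty reaction graph")
    g = graph.copy()
    removed: list[str] = []
    if exclude:
        for node in exclude:
            if node in g:
                g.remove_node(node)
                removed.append(node)
    if max_degree is not None:
        hubs = [n for n, d in g.degree() if d > max_degree]
        g.remove_nodes_from(hubs)
        removed.extend(hubs)
    nodes = sorted(g.nodes())
    if not nodes:
        raise ValidationError("conversion_distances: all nodes removed")
    dist = pd.DataFrame(NON_ADJACENT, index=nodes, columns=nodes, dtype=float)
    for source, lengths in nx.all_pairs_shortest_path_length(g):
        for target, d in lengths.items():
            dist.at[source, target] = float(d)
    return AdjacencyMatrix(dist, sorted(removed))


def neighbors_within(adj: AdjacencyMatrix, metabolite_id: str, k: int = 2) -> set[str]:
    """Metabolites within 1..k conversion steps of ``metabolite_id``."""
    if metabolite_id not in adj:
        raise KeyError(f"unknown metabolite {metabolite_id!r}")
    if k <= 0:
        return set()
    row = adj.distances.loc[metabolite_id]
    return set(row.index[(row >= 1) & (row <= k)])


def adjacency_to_long(adj: AdjacencyMatrix) -> pd.DataFrame:
    """Long-form (met_a, met_b, steps) table of finite distances, a < b."""
    rows = []
    ids = adj.metabolite_ids
    arr = adj.distances.to_numpy()
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            d = arr[i, j]
            if math.isfinite(d):
                rows.append((a, ids[j], int(d)))
    return pd.DataFrame(rows, columns=["met_a", "met_b", "steps"])


def adjacency_from_long(df: pd.DataFrame, metabolite_ids=None) -> AdjacencyMatrix:
    """Rebuild an :class:`AdjacencyMatrix` from its long-form table."""
    ids = set(df["met_a"]) | set(df["met_b"])
    if metabolite_ids is not None:
        ids |= set(metabolite_ids)
    nodes = sorted(str(i) for i in ids)
    dist = pd.DataFrame(NON_ADJACENT, index=nodes, columns=nodes, dtype=float)
    for n in nodes:
        dist.at[n, n] = 0.0
    for a, b, s in zip(df["met_a"], df["met_b"], df["steps"]):
        dist.at[str(a), str(b)] = float(s)
        dist.at[str(b), str(a)] = float(s)
    return AdjacencyMatrix(dist)
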