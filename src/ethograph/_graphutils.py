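"""Shared helpers for the directed weighted networks.

Both the individual-to-individual interaction network and the behavior
transition network carry per-edge ``weight`` and ``display`` attributes;
``display`` marks whether the edge survives the user-chosen weight
threshold (edges below it stay in the data but are hidden in drawings,
and — by design — excluded from centrality computation so that the metrics
describe the network actually shown).
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

CENTRALITY_COLUMNS = (
    "in_degree_centrality",
    "out_degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
)


def displayed_subgraph(g: nx.DiGraph) -> nx.DiGraph:
    """Copy of ``g`` with only the displayed edges (all nodes kept)."""
    h = nx.DiGraph()
    h.add_nodes_from(g.nodes(data=True))
    h.add_edges_from(
        (u, v, d) for u, v, d in g.edges(data=True) if d.get("display", True)
    )
    return h


def centrality_table(g: nx.DiGraph) -> pd.DataFrame:
    """In/out-degree, closeness and betweenness centralities of a digraph.

    Computed on the displayed edge set with self-loops removed (a
    self-interaction says nothing about an individual's position among
    others). Degree centralities are normalized by n-1; betweenness by
    (n-1)(n-2) as usual for digraphs; closeness uses *outgoing* hop
    distances from the focal node with the Wasserman–Faust
    reachable-fraction correction, so disconnected networks are handled
    gracefully. Graphs with a single node get all-zero centralities.
    """
    h = displayed_subgraph(g)
    h.remove_edges_from(nx.selfloop_edges(h))
    nodes = sorted(h.nodes())
    n = len(nodes)
    if n <= 1:
        zero = {node: 0.0 for node in nodes}
        data = {col: zero for col in CENTRALITY_COLUMNS}
    else:
        data = {
            "in_degree_centrality": nx.in_degree_centrality(h),
            "out_degree_centrality": nx.out_degree_centrality(h),
            # networkx closeness uses incoming paths; reverse for outgoing.
            "closeness_centrality": nx.closeness_centrality(h.reverse()),
            "betweenness_centrality": nx.betweenness_centrality(h, normalized=True),
        }
    table = pd.DataFrame(data, index=pd.Index(nodes, name="node"))
    return table.astype(float)
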