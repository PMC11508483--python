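"""Directed weighted interaction networks between individuals.

An edge runs from individual A to individual B when A is the subject of a
bout whose recipient (Modifier column) is B; the edge weight counts those
bouts — one bout, whether a START/STOP pair or a point event, counts as
one interaction. A display threshold hides low-weight edges from drawings
without deleting them.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from ._graphutils import CENTRALITY_COLUMNS, centrality_table
from .events import BehaviorBout


def build_interaction_network(
    bouts: Sequence[BehaviorBout],
    emitter_filter: Iterable[str] = (),
    receiver_filter: Iterable[str] = (),
    min_edge_weight: int = 0,
) -> nx.DiGraph:
    """Build the individual-to-individual interaction digraph.

    Parameters
    ----------
    bouts
        Already-filtered bouts; only recipient-bearing bouts create edges,
        but every observed subject becomes a node (a log without directed
        behavior yields isolated nodes).
    emitter_filter, receiver_filter
        Individuals to exclude as behavior emitters / receivers,
        separately (an excluded emitter may still appear as a receiver).
    min_edge_weight
        Edges with weight below this keep their weight but get
        ``display=False``.

    Self-interactions (subject == recipient) are kept as self-loops.
    """
    if min_edge_weight < 0:
        raise ValueError("min_edge_weight must be >= 0")
    emitters_excluded = set(emitter_filter)
    receivers_excluded = set(receiver_filter)
    g = nx.DiGraph(kind="interaction", min_edge_weight=min_edge_weight)
    for bout in bouts:
        if bout.subject not in emitters_excluded:
            g.add_node(bout.subject)
        if bout.recipient and bout.recipient not in receivers_excluded:
            g.add_node(bout.recipient)
        if (
            bout.recipient
            and bout.subject not in emitters_excluded
            and bout.recipient not in receivers_excluded
        ):
            if g.has_edge(bout.subject, bout.recipient):
                g[bout.subject][bout.recipient]["weight"] += 1
            else:
                g.add_edge(bout.subject, bout.recipient, weight=1)
    for _, _, d in g.edges(data=True):
        d["display"] = d["weight"] >= min_edge_weight
    return g


def interaction_node_metrics(g: nx.DiGraph) -> pd.DataFrame:
    """Node attribute and centrality table for an interaction network.

    ``out_edges``/``in_edges`` count distinct partners (edges) and
    ``out_interactions``/``in_interactions`` sum the edge weights, all on
    the full edge set so that the totals balance the number of
    recipient-bearing bouts regardless of the display threshold. The four
    centralities are computed on the displayed subgraph (self-loops
    excluded); see :func:`ethograph._graphutils.centrality_table`.
    """
    if g.number_of_nodes() == 0:
        cols = [
            "out_edges",
            "in_edges",
            "out_interactions",
            "in_interactions",
            *CENTRALITY_COLUMNS,
        ]
        return pd.DataFrame(columns=cols)
    nodes = sorted(g.nodes())
    counts = pd.DataFrame(
        {
            "out_edges": [g.out_degree(n) for n in nodes],
            "in_edges": [g.in_degree(n) for n in nodes],
            "out_interactions": [g.out_degree(n, weight="weight") for n in nodes],
            "in_interactions": [g.in_degree(n, weight="weight") for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    return counts.join(centrality_table(g))
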