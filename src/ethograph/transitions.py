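"""Behavior transition networks.

Nodes are behaviors (or behavioral categories); a directed edge a -> b
counts how often behavior b immediately followed behavior a within one
individual's bout sequence, accumulated over all selected individuals. A
self-loop records a behavior that was halted and resumed with nothing in
between. Edge weights are either these absolute succession counts or
relative transitional frequencies — each outgoing weight divided by the
sum of all outgoing weights of its source node (self-loops included in the
denominator), so outgoing frequencies sum to 1 per node.

Display thresholding only hides edges from drawings: relative frequencies
are always computed on the full edge set first, so hiding an edge never
distorts the remaining frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import networkx as nx
import pandas as pd

from ._graphutils import CENTRALITY_COLUMNS, centrality_table
from .events import BehaviorBout
from .summaries import GroupBy, _label, _label_check

WeightMode = Literal["absolute", "relative"]


def behavior_sequences(
    bouts: Sequence[BehaviorBout], node_mode: GroupBy = "behavior"
) -> dict[str, list[str]]:
    """Per-subject behavior label sequences, ordered by bout start time.

    Ties in start time are broken by original row order. In category mode
    each behavior is replaced by its category. No transitions ever cross
    subjects.
    """
    _label_check(node_mode)
    sequences: dict[str, list[str]] = {}
    for b in sorted(bouts, key=lambda b: (b.start, b.row_index)):
        sequences.setdefault(b.subject, []).append(_label(b, node_mode))
    return sequences


@dataclass
class TransitionEdgeList:
    """(from, to, weight) triples plus the weight mode.

    Absolute mode: integer succession counts >= 1. Relative mode: per
    source node the outgoing weights sum to 1.
    """

    entries: list[tuple[str, str, float]]
    mode: WeightMode = "absolute"


def count_transitions(sequences: Mapping[str, list[str]]) -> TransitionEdgeList:
    """Accumulate adjacent-pair counts over all subjects' sequences.

    A sequence of length L contributes L-1 transitions; sequences of
    length <= 1 contribute nothing. Entries are sorted lexicographically
    for deterministic output.
    """
    counts: dict[tuple[str, str], int] = {}
    for seq in sequences.values():
        for a, b in zip(seq, seq[1:]):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    entries = [(a, b, float(w)) for (a, b), w in sorted(counts.items())]
    return TransitionEdgeList(entries=entries, mode="absolute")


def relative_frequencies(edges: TransitionEdgeList) -> TransitionEdgeList:
    """Convert absolute succession counts to transitional frequencies.

    Each weight is divided by the sum of all outgoing weights of its
    source node (the edge itself and any self-loop included), so outgoing
    frequencies sum to 1 for every node with outgoing edges.
    """
    if edges.mode != "absolute":
        raise ValueError("relative_frequencies expects an absolute-mode edge list")
    out_sums: dict[str, float] = {}
    for a, _, w in edges.entries:
        out_sums[a] = out_sums.get(a, 0.0) + w
    entries = [(a, b, w / out_sums[a]) for a, b, w in edges.entries]
    return TransitionEdgeList(entries=entries, mode="relative")


def build_transition_graph(
    bouts: Sequence[BehaviorBout],
    node_mode: GroupBy = "behavior",
    weight_mode: WeightMode = "absolute",
    display_threshold: float = 0.0,
    name: str = "",
) -> nx.DiGraph:
    """Build the behavior transition digraph from filtered bouts.

    Every label observed in the sequences becomes a node (labels occurring
    only in length-1 sequences are isolated nodes). In relative mode the
    frequencies are computed on the full edge set *before* thresholding;
    the threshold only toggles per-edge ``display`` flags, evaluated on the
    chosen weight mode.
    """
    if display_threshold < 0:
        raise ValueError("display_threshold must be >= 0")
    if weight_mode not in ("absolute", "relative"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    sequences = behavior_sequences(bouts, node_mode)
    edges = count_transitions(sequences)
    if weight_mode == "relative":
        edges = relative_frequencies(edges)
    g = nx.DiGraph(
        kind="transition",
        node_mode=node_mode,
        weight_mode=weight_mode,
        display_threshold=display_threshold,
        name=name,
    )
    for seq in sequences.values():
        g.add_nodes_from(seq)
    for a, b, w in edges.entries:
        g.add_edge(a, b, weight=w, display=w >= display_threshold)
    return g


def to_relative(g: nx.DiGraph) -> nx.DiGraph:
    """Return a copy of an absolute-mode transition graph in relative mode."""
    if g.graph.get("weight_mode") == "relative":
        return g.copy()
    h = g.copy()
    h.graph["weight_mode"] = "relative"
    for node in h.nodes():
        out = list(h.out_edges(node, data=True))
        total = sum(d["weight"] for _, _, d in out)
        for _, _, d in out:
            d["weight"] = d["weight"] / total
    threshold = h.graph.get("display_threshold", 0.0)
    for _, _, d in h.edges(data=True):
        d["display"] = d["weight"] >= threshold
    return h


def transition_node_stats(
    bouts: Sequence[BehaviorBout], g: nx.DiGraph
) -> pd.DataFrame:
    """Node attribute and centrality table for a transition network.

    ``total_time`` sums the durations of the node's bouts over all
    selected subjects, ``occurrences`` counts them, and ``average_time``
    is their ratio (0 when a label has no bouts). ``in_transitions`` /
    ``out_transitions`` count distinct incident edges on the full edge
    set; centralities follow the displayed subgraph, as in the interaction
    network.
    """
    node_mode = g.graph.get("node_mode", "behavior")
    nodes = sorted(g.nodes())
    total = dict.fromkeys(nodes, 0.0)
    occ = dict.fromkeys(nodes, 0)
    for b in bouts:
        label = _label(b, node_mode)
        if label in total:
            total[label] += b.duration
            occ[label] += 1
    table = pd.DataFrame(
        {
            "total_time": [total[n] for n in nodes],
            "average_time": [
                total[n] / occ[n] if occ[n] else 0.0 for n in nodes
            ],
            "occurrences": [occ[n] for n in nodes],
            "in_transitions": [g.in_degree(n) for n in nodes],
            "out_transitions": [g.out_degree(n) for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    return table.join(centrality_table(g))


def style_map(
    values: Mapping[str, float],
    output_range: tuple[float, float],
    normalization: Literal["linear", "log"] = "linear",
) -> dict[str, float]:
    """Map nonnegative values onto an output range for drawing.

    Linear: ``v -> lo + (hi-lo) * (v-vmin)/(vmax-vmin)``. Log: the same
    after replacing every value by ``ln(1+v)``. Constant inputs map to the
    midpoint of the range (there is nothing to rank). Used for node size,
    color saturation, numeric labels and edge widths alike.
    """
    lo, hi = output_range
    if not (hi > lo >= 0):
        raise ValueError("output_range must satisfy hi > lo >= 0")
    if normalization not in ("linear", "log"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if any(v < 0 for v in values.values()):
        raise ValueError("style_map requires nonnegative values")
    if not values:
        return {}
    transform = (lambda v: math.log1p(v)) if normalization == "log" else (lambda v: v)
    tv = {k: transform(v) for k, v in values.items()}
    vmin, vmax = min(tv.values()), max(tv.values())
    if vmax == vmin:
        mid = (lo + hi) / 2.0
        return {k: mid for k in values}
    return {k: lo + (hi - lo) * (v - vmin) / (vmax - vmin) for k, v in tv.items()}


def edge_widths(
    g: nx.DiGraph,
    edge_width_factor: float = 4.0,
    normalization: Literal["linear", "log"] = "linear",
    base_width: float = 1.0,
) -> dict[tuple[str, str], float]:
    """Weight-dependent edge widths in ``[base, base + factor]``.

    The factor controls the width range spanned between the lightest and
    heaviest edge; a factor of 0 is rejected (use a fixed width instead).
    """
    if edge_width_factor <= 0:
        raise ValueError("edge_width_factor must be > 0")
    weights = {(u, v): d["weight"] for u, v, d in g.edges(data=True)}
    if not weights:
        return {}
    return style_map(
        weights, (base_width, base_width + edge_width_factor), normalization
    )
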