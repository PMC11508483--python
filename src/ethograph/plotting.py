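"""SVG figure rendering with matplotlib.

Every function returns a matplotlib Figure; callers save via
``fig.savefig(path, format="svg")`` (the CLI does this through
:class:`ethograph.export.ExportBundle`). Network drawings use a seeded
networkx spring layout so identical inputs give identical pictures.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .compare import DistanceMatrix, Embedding2D, MergeTree
from .summaries import IntervalTracks, StepSeries


def plot_counts(table: pd.DataFrame, kind: str = "bar", value: str = "count"):
    """Bar chart of absolute counts/durations, or pie of the relative ones."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    if kind == "pie":
        col = f"relative_{value}" if not value.startswith("relative_") else value
        ax.pie(table[col], labels=list(table.index), autopct="%1.1f%%")
    else:
        ax.bar(table.index, table[value])
        ax.set_ylabel(value.replace("_", " "))
        ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    return fig


def plot_timeline(tracks: IntervalTracks):
    """Horizontal bars per behavior track; point events drawn as markers."""
    labels = sorted(tracks.tracks)
    fig, ax = plt.subplots(figsize=(8, 0.5 * max(len(labels), 2) + 1.5))
    for y, label in enumerate(labels):
        for start, stop in tracks.tracks[label]:
            if stop > start:
                ax.barh(y, stop - start, left=start, height=0.6)
            else:
                ax.plot(start, y, marker="|", markersize=12, color="C3")
    ax.set_yticks(range(len(labels)), labels)
    ax.set_xlabel("time (s)")
    ax.set_title(f"subject {tracks.subject}")
    fig.tight_layout()
    return fig


def plot_occurrences(series: Sequence[StepSeries]):
    """Cumulative step curves, one line per series key."""
    fig, ax = plt.subplots(figsize=(8, 5))
    for s in series:
        times = [t for t, _ in s.points]
        counts = [c for _, c in s.points]
        ax.step([0] + times, [0] + counts, where="post", label="|".join(s.key))
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cumulative count")
    ax.legend(fontsize="small", ncols=2)
    fig.tight_layout()
    return fig


def plot_network(
    g: nx.DiGraph,
    node_sizes: Mapping[str, float] | None = None,
    edge_widths: Mapping[tuple[str, str], float] | None = None,
    seed: int = 0,
):
    """Draw the displayed edges of a digraph with a seeded spring layout."""
    fig, ax = plt.subplots(figsize=(7, 7))
    shown = [(u, v) for u, v, d in g.edges(data=True) if d.get("display", True)]
    pos = nx.spring_layout(g, seed=seed)
    sizes = [300 * (node_sizes.get(n, 1.0) if node_sizes else 1.0) for n in g.nodes()]
    widths = [edge_widths.get(e, 1.0) if edge_widths else 1.0 for e in shown]
    nx.draw_networkx_nodes(g, pos, ax=ax, node_size=sizes, node_color="#9ecae1")
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=8)
    nx.draw_networkx_edges(g, pos, ax=ax, edgelist=shown, width=widths,
                           connectionstyle="arc3,rad=0.08")
    labels = {
        (u, v): f"{g[u][v]['weight']:g}" for u, v in shown
    }
    nx.draw_networkx_edge_labels(g, pos, ax=ax, edge_labels=labels, font_size=7)
    ax.axis("off")
    fig.tight_layout()
    return fig


def plot_mds(embedding: Embedding2D):
    """Scatter of the 2-D embedding with network labels."""
    fig, ax = plt.subplots(figsize=(6, 6))
    xy = embedding.coordinates
    ax.scatter(xy[:, 0], xy[:, 1])
    for label, (x, y) in zip(embedding.labels, xy):
        ax.annotate(label, (x, y), textcoords="offset points", xytext=(4, 4))
    ax.set_title(f"MDS (stress {embedding.stress:.4g})")
    fig.tight_layout()
    return fig


def plot_dendrogram(tree: MergeTree):
    """Dendrogram with branches below the color threshold colored apart."""
    fig, ax = plt.subplots(figsize=(8, 5))
    sch.dendrogram(
        tree.linkage_matrix,
        labels=tree.labels,
        color_threshold=tree.color_threshold if tree.color_threshold > 0 else None,
        ax=ax,
    )
    ax.set_ylabel("distance")
    fig.tight_layout()
    return fig


def close_all() -> None:
    plt.close("all")
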