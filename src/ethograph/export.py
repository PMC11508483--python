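"""Serialization of graphs and tables: GML, GraphViz DOT and CSV.

GML carries the full data graph (all edges, weights, display flags). DOT
is the drawing format: hidden (below-threshold) edges are emitted with
``style=invis`` so the drawn picture matches the display flags while the
file still round-trips to the full topology. A minimal reader for the
emitted DOT dialect supports round-trip checks.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd


def write_gml(g: nx.DiGraph) -> str:
    """Serialize a digraph as GML text (booleans stored as 0/1)."""
    h = nx.DiGraph(**{k: v for k, v in g.graph.items() if isinstance(v, (str, int, float))})
    h.add_nodes_from(g.nodes())
    for u, v, d in g.edges(data=True):
        attrs = dict(d)
        if "display" in attrs:
            attrs["display"] = int(bool(attrs["display"]))
        h.add_edge(u, v, **attrs)
    return "\n".join(nx.generate_gml(h)) + "\n"


def read_gml(text: str) -> nx.DiGraph:
    """Parse GML text back into a digraph, restoring boolean display flags."""
    g = nx.parse_gml(text.splitlines())
    g = nx.DiGraph(g)
    for _, _, d in g.edges(data=True):
        if "display" in d:
            d["display"] = bool(d["display"])
    return g


def _quote(s: str) -> str:
    return '"' + str(s).replace("\\", "\\\\").replace('"', '\\"') + '"'


def write_dot(
    g: nx.DiGraph,
    node_sizes: Mapping[str, float] | None = None,
    node_saturations: Mapping[str, float] | None = None,
    node_labels: Mapping[str, object] | None = None,
    node_colors: Mapping[str, str] | None = None,
    edge_widths: Mapping[tuple[str, str], float] | None = None,
    hue: float = 0.58,
    name: str = "ethograph",
) -> str:
    """Serialize a digraph as GraphViz DOT with optional style mappings.

    Node size maps to ``width``/``height`` (inches), saturation to an HSV
    ``fillcolor`` at the given hue (overridden by an explicit per-category
    ``node_colors`` entry), values to an in-node ``label``, and edge
    widths to ``penwidth``. Edge weights always appear as edge labels;
    non-displayed edges are kept with ``style=invis``.
    """
    lines = [f"digraph {_quote(name)} {{", "  node [style=filled];"]
    for node in sorted(g.nodes(), key=str):
        attrs = []
        if node_labels is not None and node in node_labels:
            nl = "\\n"
            attrs.append(f"label={_quote(f'{node}{nl}{node_labels[node]}')}")
        if node_sizes is not None and node in node_sizes:
            size = node_sizes[node]
            attrs.append(f"width={size:.3f}")
            attrs.append(f"height={size:.3f}")
            attrs.append("fixedsize=true")
        if node_colors is not None and node in node_colors:
            attrs.append(f"fillcolor={_quote(node_colors[node])}")
        elif node_saturations is not None and node in node_saturations:
            attrs.append(
                f"fillcolor={_quote(f'{hue:.3f} {node_saturations[node]:.3f} 1.000')}"
            )
        suffix = f" [{', '.join(attrs)}]" if attrs else ""
        lines.append(f"  {_quote(node)}{suffix};")
    for u, v, d in sorted(g.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
        weight = d.get("weight", 1)
        label = f"{weight:g}" if isinstance(weight, float) else str(weight)
        attrs = [f"label={_quote(label)}", f"weight_value={weight!r}"]
        if edge_widths is not None and (u, v) in edge_widths:
            attrs.append(f"penwidth={edge_widths[(u, v)]:.3f}")
        if not d.get("display", True):
            attrs.append("style=invis")
        lines.append(f"  {_quote(u)} -> {_quote(v)} [{', '.join(attrs)}];")
    lines.append("}")
    return "\n".join(lines) + "\n"


_DOT_EDGE = re.compile(r'^\s*"((?:[^"\\]|\\.)*)"\s*->\s*"((?:[^"\\]|\\.)*)"\s*\[(.*)\];')
_DOT_NODE = re.compile(r'^\s*"((?:[^"\\]|\\.)*)"(?:\s*\[.*\])?;')


def _unquote(s: str) -> str:
    return s.replace('\\"', '"').replace("\\\\", "\\")


def read_dot(text: str) -> nx.DiGraph:
    """Parse the DOT dialect emitted by :func:`write_dot` (round-trip aid)."""
    g = nx.DiGraph()
    for line in text.splitlines():
        edge = _DOT_EDGE.match(line)
        if edge:
            u, v, attrs = _unquote(edge.group(1)), _unquote(edge.group(2)), edge.group(3)
            weight_match = re.search(r"weight_value=([0-9.eE+-]+)", attrs)
            weight = float(weight_match.group(1)) if weight_match else 1.0
            if weight == int(weight):
                weight = int(weight)
            g.add_edge(u, v, weight=weight, display="style=invis" not in attrs)
            continue
        node = _DOT_NODE.match(line)
        if node and node.group(1) != "node":
            g.add_node(_unquote(node.group(1)))
    return g


def write_metrics_csv(table: pd.DataFrame) -> str:
    """Serialize a per-node metrics table as CSV (header always present)."""
    return table.to_csv()


@dataclass
class ExportBundle:
    """Files produced by one CLI invocation, with a manifest."""

    out_dir: Path
    files: list[str] = field(default_factory=list)

    def add(self, filename: str, content: str) -> Path:
        path = self.out_dir / filename
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(content)
        self.files.append(filename)
        return path

    def add_figure(self, filename: str, fig) -> Path:
        path = self.out_dir / filename
        path.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path, format="svg")
        self.files.append(filename)
        return path

    def write_manifest(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps({"files": sorted(self.files)}, indent=2) + "\n")
        return path
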