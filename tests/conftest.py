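from __future__ import annotations

import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

from ethograph.events import BehaviorBout

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


SIMPLE_CSV = """Time,Subject,Behavior,Status,Modifier,Behavioral category
0.0,s1,Digging,START,,Maintenance
5.0,s1,Digging,STOP,,Maintenance
3.0,s1,Ramming,POINT,s2,Aggression
6.0,s1,S-Bend,START,s2,Aggression
7.0,s1,S-Bend,STOP,s2,Aggression
2.0,s2,Digging,START,,Maintenance
4.0,s2,Digging,STOP,,Maintenance
"""


@pytest.fixture
def simple_csv(tmp_path):
    path = tmp_path / "log.csv"
    path.write_text(SIMPLE_CSV)
    return path


def make_bout(subject, behavior, start, stop, category="None", recipient="", row=0):
    return BehaviorBout(
        subject=subject,
        behavior=behavior,
        start=start,
        stop=stop,
        category=category,
        recipient=recipient,
        row_index=row,
    )


def make_transition_graph(edges, name="", nodes=(), weight_mode="absolute"):
    """Transition digraph from (from, to, weight) triples."""
    g = nx.DiGraph(
        kind="transition", node_mode="behavior", weight_mode=weight_mode, name=name
    )
    g.add_nodes_from(nodes)
    for a, b, w in edges:
        g.add_edge(a, b, weight=w, display=True)
    return g


def random_transition_graph(rng: np.random.Generator, max_nodes=8, name=""):
    """Random weighted digraph fixture (self-loops allowed)."""
    n = int(rng.integers(3, max_nodes + 1))
    p = float(rng.uniform(0.2, 0.6))
    edges = []
    for u in range(n):
        for v in range(n):
            if rng.random() < p:
                edges.append((f"b{u}", f"b{v}", int(rng.integers(1, 9))))
    return make_transition_graph(edges, name=name, nodes=[f"b{i}" for i in range(n)])
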