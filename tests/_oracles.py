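"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately written by a different route than the
package: BFS dictionaries and explicit path enumeration instead of
networkx, Floyd–Warshall portraits, trapezoid integration with bisection
calibration for the spectral distance, and the explicit 2m x 2m
edge-to-edge non-backtracking matrix. Sizes are tiny, so clarity beats
speed throughout.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np


# ---------------------------------------------------------------------------
# Centralities on a directed graph given as an edge set (no self-loops).

def _bfs_dists(nodes, edges, source):
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def _all_shortest_paths(nodes, edges, s, t):
    """All shortest s->t paths by exhaustive simple-path enumeration."""
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
    dist = _bfs_dists(nodes, edges, s)
    if t not in dist or s == t:
        return []
    target_len = dist[t]
    paths = []

    def walk(path):
        u = path[-1]
        if u == t:
            if len(path) - 1 == target_len:
                paths.append(list(path))
            return
        if len(path) - 1 >= target_len:
            return
        for v in adj[u]:
            if v not in path:
                walk(path + [v])

    walk([s])
    return paths


def brute_centralities(nodes, edges):
    """In/out-degree, closeness (outgoing, reachable-fraction corrected)
    and betweenness centralities by direct enumeration."""
    nodes = sorted(nodes)
    edges = {(u, v) for u, v in edges if u != v}
    n = len(nodes)
    out = {}
    for v in nodes:
        if n <= 1:
            out[v] = (0.0, 0.0, 0.0, 0.0)
            continue
        in_deg = sum(1 for u, w in edges if w == v) / (n - 1)
        out_deg = sum(1 for u, w in edges if u == v) / (n - 1)
        dist = _bfs_dists(nodes, edges, v)
        reach = {u: d for u, d in dist.items() if u != v}
        if reach:
            closeness = (len(reach) / (n - 1)) * (len(reach) / sum(reach.values()))
        else:
            closeness = 0.0
        btw = 0.0
        if n > 2:
            for s, t in itertools.permutations(nodes, 2):
                if v in (s, t):
                    continue
                paths = _all_shortest_paths(nodes, edges, s, t)
                if paths:
                    btw += sum(1 for p in paths if v in p[1:-1]) / len(paths)
            btw /= (n - 1) * (n - 2)
        out[v] = (in_deg, out_deg, closeness, btw)
    return out


# ---------------------------------------------------------------------------
# Distance-measure oracles over aligned adjacency matrices.

def _sym_binary(a):
    s = ((np.asarray(a) > 0) | (np.asarray(a).T > 0)).astype(float)
    np.fill_diagonal(s, 0.0)
    return s


def _jsd_bits_oracle(p: Counter, q: Counter) -> float:
    zp = sum(p.values())
    zq = sum(q.values())
    if zp == 0 or zq == 0:
        return 0.0
    keys = set(p) | set(q)
    total = 0.0
    for pp, zz, other, zo in ((p, zp, q, zq), (q, zq, p, zp)):
        for k in keys:
            pk = pp[k] / zz
            if pk == 0:
                continue
            mk = 0.5 * (pk + other[k] / zo)
            total += 0.5 * pk * math.log2(pk / mk)
    return total


def frobenius_oracle(a1, a2):
    total = 0.0
    for i in range(len(a1)):
        for j in range(len(a1)):
            total += (a1[i][j] - a2[i][j]) ** 2
    return math.sqrt(total)


def hamming_oracle(a1, a2):
    n = len(a1)
    if n == 0:
        return 0.0
    diff = sum(
        (a1[i][j] > 0) != (a2[i][j] > 0) for i in range(n) for j in range(n)
    )
    return diff / n**2


def degree_oracle(a1, a2):
    s1, s2 = _sym_binary(a1), _sym_binary(a2)
    c1 = Counter(int(d) for d in s1.sum(axis=1))
    c2 = Counter(int(d) for d in s2.sum(axis=1))
    return _jsd_bits_oracle(c1, c2)


def _portrait_counter(a) -> Counter:
    """Joint (distance, shell-size) distribution weighted by shell size,
    via Floyd–Warshall."""
    s = _sym_binary(a)
    n = s.shape[0]
    d = np.where(s > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    weights: Counter = Counter()
    weights[(0, 1)] = n * 1  # each node sees itself; weight k=1 each
    max_l = int(d[np.isfinite(d)].max()) if n else 0
    for l in range(1, max_l + 1):
        for i in range(n):
            k = int(np.sum(d[i] == l))
            weights[(l, k)] += k
    return weights


def portrait_oracle(a1, a2):
    return _jsd_bits_oracle(_portrait_counter(a1), _portrait_counter(a2))


# ---------------------------------------------------------------------------
# Ipsen–Mikhailov oracle: trapezoid grid + bisection gamma calibration.

def _omegas(a):
    s = _sym_binary(a)
    if s.shape[0] < 2:
        return np.zeros(0)
    lap = np.diag(s.sum(axis=1)) - s
    ev = np.clip(np.linalg.eigvalsh(lap), 0, None)
    return np.sqrt(ev[1:])


def _im_grid_distance(f1, f2, gamma, wmax):
    grid = np.linspace(0.0, wmax, 200_001)

    def density(freqs):
        if freqs.size == 0:
            return np.zeros_like(grid)
        dens = np.sum(
            gamma / ((grid[:, None] - freqs[None, :]) ** 2 + gamma**2), axis=1
        )
        norm = np.sum(np.pi / 2 + np.arctan(freqs / gamma))
        return dens / norm

    diff = density(np.asarray(f1)) - density(np.asarray(f2))
    return math.sqrt(np.trapezoid(diff**2, grid))


def im_oracle(a1, a2):
    n = len(a1)
    if n < 2:
        return 0.0
    empty = np.zeros(n - 1)
    complete = np.full(n - 1, math.sqrt(n))
    wmax = math.sqrt(n) + 60.0

    lo, hi = 1e-3, 5.0
    for _ in range(60):  # bisection on the calibration equation
        mid = 0.5 * (lo + hi)
        if _im_grid_distance(empty, complete, mid, wmax) > 1.0:
            lo = mid
        else:
            hi = mid
    gamma = 0.5 * (lo + hi)
    return _im_grid_distance(_omegas(a1), _omegas(a2), gamma, wmax)


# ---------------------------------------------------------------------------
# Non-backtracking oracle: explicit 2m x 2m edge-to-edge matrix.

def nb_eigenvalues_explicit(a):
    s = _sym_binary(a)
    n = s.shape[0]
    arcs = [(u, v) for u in range(n) for v in range(n) if s[u, v] > 0]
    if not arcs:
        return np.zeros(0, dtype=complex)
    index = {arc: i for i, arc in enumerate(arcs)}
    b = np.zeros((len(arcs), len(arcs)))
    for (u, v), i in index.items():
        for (x, y), j in index.items():
            if v == x and y != u:
                b[i, j] = 1.0
    return np.linalg.eigvals(b)


def assignment_emd_oracle(c1, c2):
    """Optimal-assignment EMD; exhaustive permutations for small clouds,
    scipy assignment otherwise (the cloud construction is the independent
    part under test)."""
    k = max(len(c1), len(c2))
    if k == 0:
        return 0.0
    e1 = np.zeros(k, dtype=complex)
    e1[: len(c1)] = c1
    e2 = np.zeros(k, dtype=complex)
    e2[: len(c2)] = c2
    if k <= 6:
        best = math.inf
        for perm in itertools.permutations(range(k)):
            cost = sum(abs(e1[i] - e2[p]) for i, p in enumerate(perm)) / k
            best = min(best, cost)
        return best
    from scipy.optimize import linear_sum_assignment

    cost = np.abs(e1[:, None] - e2[None, :])
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].mean())


def nbd_oracle(a1, a2):
    return assignment_emd_oracle(
        nb_eigenvalues_explicit(a1), nb_eigenvalues_explicit(a2)
    )


# ---------------------------------------------------------------------------
# Enumeration of small labeled digraphs.

def all_digraphs(n):
    """Yield the edge sets of every labeled digraph on nodes 0..n-1
    (self-loops excluded)."""
    pairs = [(u, v) for u in range(n) for v in range(n) if u != v]
    for mask in range(2 ** len(pairs)):
        yield [pairs[i] for i in range(len(pairs)) if mask >> i & 1]


def adjacency(n, edges, weights=None):
    a = np.zeros((n, n))
    for idx, (u, v) in enumerate(edges):
        a[u, v] = 1.0 if weights is None else weights[idx]
    return a
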