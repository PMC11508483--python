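"""Pairwise comparison and clustering of behavior transition networks.

Networks built from different recordings rarely share a behavior
repertoire, so each pair is first aligned over the union of the two node
label sets (absent behaviors become isolated zero rows — a differing
repertoire is itself signal). Six graph distance measures are available:

- ``portrait``: Network Portrait Divergence — Jensen–Shannon divergence
  (base 2) between the shortest-path "portrait" distributions of the
  symmetrized, binarized graphs.
- ``frobenius``: entrywise l2 norm of the difference of the directed
  weighted adjacency matrices.
- ``hamming``: fraction of differing entries of the directed binarized
  adjacency matrices over all n^2 positions (diagonal included — self
  loops are meaningful transitions).
- ``degree``: Degree Divergence — base-2 Jensen–Shannon divergence
  between the total-degree distributions of the symmetrized binarized
  graphs.
- ``ipsen_mikhailov``: Ipsen–Mikhailov spectral distance — L2 distance
  between Lorentzian-broadened Laplacian vibrational spectra, with the
  common width gamma calibrated per node count so that the empty and the
  complete graph are at distance exactly 1.
- ``nbd``: distributional non-backtracking spectral distance — earth-mover
  (optimal assignment) distance between the complex eigenvalue clouds of
  the two graphs' non-backtracking operators.

The spectral and portrait measures are defined for undirected unweighted
graphs and therefore operate on the symmetrized binarized adjacency; the
matrix-norm measures extend naturally to directed (and, for Frobenius,
weighted) matrices. The resulting distance matrix feeds a deterministic
SMACOF multidimensional scaling and scipy agglomerative clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.integrate
import scipy.optimize
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform

from .transitions import to_relative

Linkage = Literal["average", "complete", "single"]

__all__ = [
    "AlignedPair",
    "align_pair",
    "portrait_divergence",
    "frobenius_distance",
    "hamming_distance",
    "degree_divergence",
    "ipsen_mikhailov",
    "nbd_distance",
    "MEASURES",
    "DistanceMatrix",
    "pairwise_distance_matrix",
    "network_labels",
    "Embedding2D",
    "mds_embed",
    "MergeTree",
    "hierarchical_clustering",
]


# ---------------------------------------------------------------------------
# Alignment

@dataclass
class AlignedPair:
    """Two adjacency matrices over the union of two graphs' node labels.

    Labels are sorted lexicographically; a node absent from one graph
    contributes a zero row/column there.
    """

    labels: list[str]
    a1: np.ndarray
    a2: np.ndarray
    weight_mode: str = "absolute"

    def binarized(self) -> tuple[np.ndarray, np.ndarray]:
        return (self.a1 > 0).astype(float), (self.a2 > 0).astype(float)

    def symmetrized_binary(self) -> tuple[np.ndarray, np.ndarray]:
        """Undirected unweighted versions (self-loops dropped)."""
        out = []
        for a in self.binarized():
            s = ((a + a.T) > 0).astype(float)
            np.fill_diagonal(s, 0.0)
            out.append(s)
        return out[0], out[1]


def align_pair(
    g1: nx.DiGraph, g2: nx.DiGraph, weight_mode: str | None = None
) -> AlignedPair:
    """Label-match two transition graphs over their union node set.

    When ``weight_mode`` is given and differs from a graph's stored mode,
    the graph is converted (absolute counts -> relative frequencies) before
    its adjacency matrix is taken.
    """
    graphs = []
    for g in (g1, g2):
        if weight_mode == "relative" and g.graph.get("weight_mode") != "relative":
            g = to_relative(g)
        graphs.append(g)
    labels = sorted(set(graphs[0].nodes()) | set(graphs[1].nodes()), key=str)
    mats = []
    for g in graphs:
        if set(g.nodes()) != set(labels):
            g = g.copy()
            g.add_nodes_from(labels)  # absent behaviors become zero rows
        mats.append(nx.to_numpy_array(g, nodelist=labels, weight="weight"))
    mode = weight_mode or graphs[0].graph.get("weight_mode", "absolute")
    return AlignedPair(labels=list(map(str, labels)), a1=mats[0], a2=mats[1],
                       weight_mode=mode)


# ---------------------------------------------------------------------------
# Shared numerics

def _jsd_bits(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen–Shannon divergence in bits between two discrete distributions."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.sum() == 0 or q.sum() == 0:
        return 0.0
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)

    def kl(a: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / m[mask])))

    return 0.5 * kl(p) + 0.5 * kl(q)


# ---------------------------------------------------------------------------
# Portrait divergence

def _portrait(a_sym: np.ndarray) -> np.ndarray:
    """Network portrait B[l, k]: number of nodes with exactly k nodes at
    unweighted shortest-path distance l. Row 0 is B[0, 1] = n."""
    n = a_sym.shape[0]
    if n == 0:
        return np.zeros((1, 1))
    g = nx.from_numpy_array(a_sym, create_using=nx.Graph)
    rows: list[dict[int, int]] = [{1: n}]  # l = 0: each node sees itself
    max_l = 0
    shells_per_node = []
    for node in g.nodes():
        lengths = nx.single_source_shortest_path_length(g, node)
        shell: dict[int, int] = {}
        for dist in lengths.values():
            if dist > 0:
                shell[dist] = shell.get(dist, 0) + 1
        shells_per_node.append(shell)
        if shell:
            max_l = max(max_l, max(shell))
    B = np.zeros((max_l + 1, n + 1))
    B[0, 1] = n
    for l in range(1, max_l + 1):
        for shell in shells_per_node:
            B[l, shell.get(l, 0)] += 1
    return B


def _portrait_distribution(B: np.ndarray) -> np.ndarray:
    # P(l, k) proportional to k * B[l, k]: probability that a random
    # ordered node pair lies at distance l with the source having k
    # neighbors in that shell.
    k = np.arange(B.shape[1])
    return (B * k[None, :]).ravel()


def portrait_divergence(p: AlignedPair) -> float:
    """Network Portrait Divergence of the symmetrized binarized pair, in [0, 1]."""
    s1, s2 = p.symmetrized_binary()
    B1, B2 = _portrait(s1), _portrait(s2)
    L = max(B1.shape[0], B2.shape[0])
    K = max(B1.shape[1], B2.shape[1])
    P1 = np.zeros((L, K))
    P1[: B1.shape[0], : B1.shape[1]] = B1
    P2 = np.zeros((L, K))
    P2[: B2.shape[0], : B2.shape[1]] = B2
    return _jsd_bits(_portrait_distribution(P1), _portrait_distribution(P2))


# ---------------------------------------------------------------------------
# Matrix-norm measures

def frobenius_distance(p: AlignedPair) -> float:
    """Entrywise l2 norm of the weighted directed adjacency difference."""
    return float(np.linalg.norm(p.a1 - p.a2))


def hamming_distance(p: AlignedPair) -> float:
    """Fraction of differing entries of the binarized directed matrices."""
    b1, b2 = p.binarized()
    n = b1.shape[0]
    if n == 0:
        return 0.0
    return float(np.mean(b1 != b2))


def degree_divergence(p: AlignedPair) -> float:
    """Base-2 JSD between the symmetrized graphs' total-degree distributions."""
    s1, s2 = p.symmetrized_binary()
    d1 = s1.sum(axis=1).astype(int)
    d2 = s2.sum(axis=1).astype(int)
    if d1.size == 0:
        return 0.0
    kmax = int(max(d1.max(initial=0), d2.max(initial=0)))
    h1 = np.bincount(d1, minlength=kmax + 1)
    h2 = np.bincount(d2, minlength=kmax + 1)
    return _jsd_bits(h1, h2)


# ---------------------------------------------------------------------------
# Ipsen–Mikhailov

def _vibrational_frequencies(a_sym: np.ndarray) -> np.ndarray:
    """omega_i = sqrt(lambda_i) of the graph Laplacian, smallest (zero)
    eigenvalue dropped."""
    n = a_sym.shape[0]
    if n < 2:
        return np.zeros(0)
    lap = np.diag(a_sym.sum(axis=1)) - a_sym
    eig = np.linalg.eigvalsh(lap)
    eig = np.clip(eig, 0.0, None)
    return np.sqrt(eig[1:])


def _im_distance_freqs(f1: np.ndarray, f2: np.ndarray, gamma: float) -> float:
    """L2 distance between the two Lorentzian spectral densities on [0, inf).

    Each density is a sum of Lorentzians of width gamma centered at the
    vibrational frequencies, normalized to unit mass using the closed form
    integral of a Lorentzian over [0, inf): pi/2 + arctan(w / gamma).
    """

    def norm(freqs: np.ndarray) -> float:
        return float(np.sum(np.pi / 2 + np.arctan(freqs / gamma)))

    n1 = norm(f1) if f1.size else 1.0
    n2 = norm(f2) if f2.size else 1.0

    def dens(w: float, freqs: np.ndarray, z: float) -> float:
        if freqs.size == 0:
            return 0.0
        return float(np.sum(gamma / ((w - freqs) ** 2 + gamma**2)) / z)

    def integrand(w: float) -> float:
        diff = dens(w, f1, n1) - dens(w, f2, n2)
        return diff * diff

    upper = float(max(f1.max(initial=0.0), f2.max(initial=0.0)))
    cut = upper + 1.0
    head, _ = scipy.integrate.quad(
        integrand, 0, cut, limit=200, points=[upper] if 0 < upper < cut else None
    )
    tail, _ = scipy.integrate.quad(integrand, cut, np.inf, limit=200)
    return float(np.sqrt(max(head + tail, 0.0)))


@lru_cache(maxsize=None)
def _im_gamma(n: int) -> float:
    """Lorentzian width calibrated so d(empty_n, complete_n) = 1."""
    empty = np.zeros(n - 1)
    complete = np.full(n - 1, np.sqrt(n))

    def objective(gamma: float) -> float:
        return _im_distance_freqs(empty, complete, gamma) - 1.0

    return float(scipy.optimize.brentq(objective, 1e-3, 5.0, xtol=1e-9))


def ipsen_mikhailov(p: AlignedPair) -> float:
    """Ipsen–Mikhailov spectral distance on the symmetrized binarized pair.

    Returns values in [0, 1] by construction of the gamma calibration;
    graphs with fewer than two nodes are spectrally indistinguishable and
    give 0.
    """
    s1, s2 = p.symmetrized_binary()
    n = s1.shape[0]
    if n < 2:
        return 0.0
    gamma = _im_gamma(n)
    return _im_distance_freqs(
        _vibrational_frequencies(s1), _vibrational_frequencies(s2), gamma
    )


# ---------------------------------------------------------------------------
# Non-backtracking spectral distance

def nb_eigenvalues(a_sym: np.ndarray) -> np.ndarray:
    """Eigenvalues of the non-backtracking (Hashimoto) operator.

    Computed from the 2n x 2n pseudo-Hashimoto block matrix
    ``[[A, I - D], [I, 0]]`` whose spectrum, by the Ihara–Bass identity,
    equals the edge-operator spectrum up to ``|m - n|`` trivial pairs of
    eigenvalues at +1 and -1; those are added or removed so the result is
    the exact 2m-point eigenvalue cloud of the explicit edge-to-edge
    operator.
    """
    a = (np.asarray(a_sym) > 0).astype(float)
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    m = int(a.sum()) // 2
    if m == 0:
        return np.zeros(0, dtype=complex)
    d = np.diag(a.sum(axis=1))
    eye = np.eye(n)
    block = np.block([[a, eye - d], [eye, np.zeros((n, n))]])
    ev = np.linalg.eigvals(block)
    if m > n:
        extra = np.array([1.0, -1.0] * (m - n), dtype=complex)
        ev = np.concatenate([ev, extra])
    elif n > m:
        for target in (1.0, -1.0):
            for _ in range(n - m):
                idx = int(np.argmin(np.abs(ev - target)))
                ev = np.delete(ev, idx)
    return ev


def _assignment_emd(c1: np.ndarray, c2: np.ndarray) -> float:
    """Mean optimal-assignment distance between two complex point clouds,
    zero-padded to equal size."""
    k = max(c1.size, c2.size)
    if k == 0:
        return 0.0
    e1 = np.zeros(k, dtype=complex)
    e1[: c1.size] = c1
    e2 = np.zeros(k, dtype=complex)
    e2[: c2.size] = c2
    cost = np.abs(e1[:, None] - e2[None, :])
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].mean())


def nbd_distance(p: AlignedPair) -> float:
    """Distributional non-backtracking spectral distance.

    Earth-mover distance (optimal assignment, mean matched modulus
    difference) between the complex non-backtracking eigenvalue clouds of
    the symmetrized binarized graphs.
    """
    s1, s2 = p.symmetrized_binary()
    return _assignment_emd(nb_eigenvalues(s1), nb_eigenvalues(s2))


MEASURES: dict[str, Callable[[AlignedPair], float]] = {
    "portrait": portrait_divergence,
    "frobenius": frobenius_distance,
    "hamming": hamming_distance,
    "degree": degree_divergence,
    "ipsen_mikhailov": ipsen_mikhailov,
    "nbd": nbd_distance,
}


# ---------------------------------------------------------------------------
# Distance matrix

@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix over labeled networks."""

    labels: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self) -> str:
        return self.to_frame().to_csv()


def network_labels(names: Sequence[str]) -> list[str]:
    """Short display labels: the first two characters of each network
    name, enumerated on collision (``Nm``, ``Nm1``, ``Nm2`` ...)."""
    short = [str(n)[:2] if str(n) else "??" for n in names]
    labels: list[str] = []
    seen: dict[str, int] = {}
    for s in short:
        if short.count(s) > 1:
            seen[s] = seen.get(s, 0) + 1
            labels.append(f"{s}{seen[s]}")
        else:
            labels.append(s)
    return labels


def pairwise_distance_matrix(
    graphs: Sequence[nx.DiGraph],
    measure: str = "portrait",
    weight_mode: str = "absolute",
    labels: Sequence[str] | None = None,
) -> DistanceMatrix:
    """All-pairs distances between transition networks under one measure.

    The diagonal is exactly zero and the matrix exactly symmetric (each
    unordered pair is computed once). Labels default to the first two
    characters of each graph's name, enumerated on collision.
    """
    if len(graphs) < 2:
        raise ValueError("pairwise_distance_matrix needs at least 2 graphs")
    if measure not in MEASURES:
        raise ValueError(
            f"unknown measure {measure!r}; available: {sorted(MEASURES)}"
        )
    fn = MEASURES[measure]
    if labels is None:
        labels = network_labels([g.graph.get("name", "") for g in graphs])
    n = len(graphs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            val = fn(align_pair(graphs[i], graphs[j], weight_mode))
            d[i, j] = d[j, i] = val
    return DistanceMatrix(labels=list(labels), values=d)


# ---------------------------------------------------------------------------
# Multidimensional scaling (SMACOF)

@dataclass
class Embedding2D:
    """2-D metric MDS embedding; deterministic given (D, seed, n_init)."""

    coordinates: np.ndarray
    stress: float
    seed: int
    n_init: int
    labels: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coordinates, index=self.labels or None, columns=["x", "y"]
        )


def _smacof_single(
    d: np.ndarray, x: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float]:
    n = d.shape[0]
    old_stress: float | None = None
    for _ in range(max_iter):
        dis = squareform(pdist(x))
        stress = float(np.sum((d - dis) ** 2) / 2.0)
        if old_stress is not None and old_stress - stress < tol:
            break
        old_stress = stress
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dis > 0, d / dis, 0.0)
        b = -ratio
        np.fill_diagonal(b, 0.0)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = b @ x / n
    dis = squareform(pdist(x))
    return x, float(np.sum((d - dis) ** 2) / 2.0)


def mds_embed(
    dm: DistanceMatrix,
    n_init: int = 4,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> Embedding2D:
    """Metric MDS by SMACOF stress majorization, best of ``n_init`` restarts.

    Restart k draws its initial configuration from a generator seeded
    ``seed + k``, so the restart streams for different ``n_init`` are
    nested: increasing ``n_init`` can only lower (never raise) the
    returned stress, and identical ``(D, seed, n_init)`` reproduce the
    embedding bitwise.
    """
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    d = np.asarray(dm.values, dtype=float)
    scale = d.max() if d.max() > 0 else 1.0
    best_x: np.ndarray | None = None
    best_stress = np.inf
    for k in range(n_init):
        rng = np.random.default_rng(seed + k)
        x0 = rng.uniform(-scale, scale, size=(d.shape[0], 2))
        x, stress = _smacof_single(d, x0, max_iter, tol)
        if stress < best_stress:
            best_stress = stress
            best_x = x
    assert best_x is not None
    return Embedding2D(
        coordinates=best_x,
        stress=best_stress,
        seed=seed,
        n_init=n_init,
        labels=list(dm.labels),
    )


# ---------------------------------------------------------------------------
# Agglomerative clustering

@dataclass
class MergeTree:
    """Agglomerative clustering result (scipy linkage matrix + labels).

    ``color_threshold`` partitions the leaves into the maximal clusters
    merged strictly below the threshold, mirroring dendrogram branch
    coloring.
    """

    linkage_matrix: np.ndarray
    labels: list[str]
    linkage: Linkage
    color_threshold: float = 0.0

    @property
    def merges(self) -> list[tuple[int, int, float, int]]:
        return [
            (int(a), int(b), float(h), int(size))
            for a, b, h, size in self.linkage_matrix
        ]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].astype(float)

    def color_groups(self) -> list[frozenset[str]]:
        """Maximal clusters formed by merges with height strictly below
        ``color_threshold``; unmerged leaves are singleton groups."""
        n = len(self.labels)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        # cluster id -> constituent leaf indices, ids as in the linkage matrix
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        for idx, (a, b, h, _) in enumerate(self.merges):
            leaves = members[a] + members[b]
            members[n + idx] = leaves
            if h < self.color_threshold:
                parent[find(members[a][0])] = find(members[b][0])
        groups: dict[int, set[str]] = {}
        for i in range(n):
            groups.setdefault(find(i), set()).add(self.labels[i])
        return sorted(
            (frozenset(g) for g in groups.values()), key=lambda s: sorted(s)
        )


def hierarchical_clustering(
    dm: DistanceMatrix,
    linkage: Linkage = "average",
    color_threshold: float = 0.0,
) -> MergeTree:
    """Agglomerative clustering of the distance matrix.

    Standard scipy linkage under the chosen criterion (average, complete
    or single); merge heights are nondecreasing for all three on a metric
    input.
    """
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    condensed = squareform(np.asarray(dm.values, dtype=float), checks=False)
    z = sch.linkage(condensed, method=linkage)
    return MergeTree(
        linkage_matrix=z,
        labels=list(dm.labels),
        linkage=linkage,
        color_threshold=color_threshold,
    )
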