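import itertools

import numpy as np
import pytest

from ethograph.compare import (
    MEASURES,
    AlignedPair,
    align_pair,
    degree_divergence,
    frobenius_distance,
    hamming_distance,
    hierarchical_clustering,
    ipsen_mikhailov,
    mds_embed,
    nbd_distance,
    network_labels,
    pairwise_distance_matrix,
    portrait_divergence,
    DistanceMatrix,
)
from ethograph.compare import nb_eigenvalues

import _oracles
from conftest import make_transition_graph, random_transition_graph


def pair_from_matrices(a1, a2):
    n = len(a1)
    return AlignedPair(
        labels=[f"b{i}" for i in range(n)],
        a1=np.asarray(a1, dtype=float),
        a2=np.asarray(a2, dtype=float),
    )


class TestAlign:
    def test_union_labels(self):
        g1 = make_transition_graph([("A", "B", 1)])
        g2 = make_transition_graph([("B", "C", 2)])
        p = align_pair(g1, g2)
        assert p.labels == ["A", "B", "C"]
        assert p.a1.shape == (3, 3)
        assert p.a1[0, 1] == 1 and p.a2[1, 2] == 2

    def test_identical_graphs_identical_matrices(self):
        g = make_transition_graph([("A", "B", 3), ("B", "A", 1)])
        p = align_pair(g, g)
        assert np.array_equal(p.a1, p.a2)

    def test_disjoint_nodes_zero_cross_blocks(self):
        g1 = make_transition_graph([("A", "B", 1)])
        g2 = make_transition_graph([("C", "D", 1)])
        p = align_pair(g1, g2)
        assert p.a1[:2, 2:].sum() == 0 and p.a1[2:, :].sum() == 0
        assert p.a2[:2, :].sum() == 0

    def test_relative_mode_conversion(self):
        g1 = make_transition_graph([("A", "B", 3), ("A", "A", 1)])
        p = align_pair(g1, g1, weight_mode="relative")
        assert p.a1[0, 1] == pytest.approx(0.75)
        assert p.a1[0, 0] == pytest.approx(0.25)


class TestClosedFormExamples:
    def test_frobenius_one_entry(self):
        a = np.zeros((3, 3))
        b = a.copy()
        b[0, 1] = 2.5
        assert frobenius_distance(pair_from_matrices(a, b)) == pytest.approx(2.5)

    def test_frobenius_3_4_5(self):
        a = np.zeros((3, 3))
        b = a.copy()
        b[0, 1] = 3.0
        b[1, 2] = 4.0
        assert frobenius_distance(pair_from_matrices(a, b)) == pytest.approx(5.0)

    def test_hamming_complementary_two_node_digraphs(self):
        a = np.array([[1.0, 1.0], [0.0, 0.0]])
        b = np.array([[0.0, 0.0], [1.0, 1.0]])
        assert hamming_distance(pair_from_matrices(a, b)) == 1.0

    def test_hamming_one_entry_over_n_squared(self):
        a = np.zeros((3, 3))
        b = a.copy()
        b[2, 0] = 7.0
        assert hamming_distance(pair_from_matrices(a, b)) == pytest.approx(1 / 9)

    def test_degree_divergence_disjoint_point_masses(self):
        # one graph where every node has degree 1, one with all degree 0
        a = np.array([[0.0, 1.0], [0.0, 0.0]])
        b = np.zeros((2, 2))
        assert degree_divergence(pair_from_matrices(a, b)) == pytest.approx(1.0)

    def test_portrait_path_vs_triangle(self):
        path = np.array([[0, 1, 0], [0, 0, 1], [0, 0, 0]], dtype=float)
        tri = np.array([[0, 1, 1], [0, 0, 1], [0, 0, 0]], dtype=float)
        p = pair_from_matrices(path, tri)
        # hand-derived joint portrait distributions give
        # JSD = (2/9 + (2/3) log2(3/2)) / 2
        expected = (2 / 9 + (2 / 3) * np.log2(1.5)) / 2
        assert portrait_divergence(p) == pytest.approx(expected)
        assert portrait_divergence(p) == pytest.approx(
            _oracles.portrait_oracle(path, tri)
        )

    def test_ipsen_mikhailov_empty_vs_complete_is_one(self):
        for n in (4, 6):
            empty = np.zeros((n, n))
            complete = np.ones((n, n)) - np.eye(n)
            d = ipsen_mikhailov(pair_from_matrices(empty, complete))
            assert d == pytest.approx(1.0, abs=1e-6)

    def test_nbd_cycle_vs_path(self):
        cycle = np.zeros((4, 4))
        for i in range(4):
            cycle[i, (i + 1) % 4] = 1
        path = np.zeros((4, 4))
        for i in range(3):
            path[i, i + 1] = 1
        d = nbd_distance(pair_from_matrices(cycle, path))
        assert d > 0
        assert d == pytest.approx(_oracles.nbd_oracle(cycle, path), abs=1e-8)

    def test_nb_eigenvalues_match_explicit_matrix(self):
        # pseudo-Hashimoto + Ihara correction vs the explicit 2m x 2m
        # edge operator, as eigenvalue multisets
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(2, 6))
            a = (rng.random((n, n)) < 0.5).astype(float)
            np.fill_diagonal(a, 0)
            ours = np.sort_complex(np.round(nb_eigenvalues(((a + a.T) > 0) * 1.0), 6))
            theirs = np.sort_complex(
                np.round(_oracles.nb_eigenvalues_explicit(a), 6)
            )
            assert ours.shape == theirs.shape
            assert np.allclose(ours, theirs, atol=1e-4)


class TestMeasureProperties:
    @pytest.mark.parametrize("name", sorted(MEASURES))
    def test_zero_self_symmetric_nonnegative(self, name):
        fn = MEASURES[name]
        rng = np.random.default_rng(17)
        for _ in range(8):
            g1 = random_transition_graph(rng, max_nodes=6)
            g2 = random_transition_graph(rng, max_nodes=6)
            assert fn(align_pair(g1, g1)) == 0.0
            d12 = fn(align_pair(g1, g2))
            d21 = fn(align_pair(g2, g1))
            assert d12 == pytest.approx(d21, abs=1e-9)
            assert d12 >= 0

    @pytest.mark.parametrize("name", ["portrait", "degree"])
    def test_bounded_by_one(self, name):
        fn = MEASURES[name]
        rng = np.random.default_rng(23)
        for _ in range(15):
            g1 = random_transition_graph(rng, max_nodes=7)
            g2 = random_transition_graph(rng, max_nodes=7)
            assert 0.0 <= fn(align_pair(g1, g2)) <= 1.0 + 1e-12


ORACLES = {
    "portrait": _oracles.portrait_oracle,
    "frobenius": _oracles.frobenius_oracle,
    "hamming": _oracles.hamming_oracle,
    "degree": _oracles.degree_oracle,
    "ipsen_mikhailov": _oracles.im_oracle,
    "nbd": _oracles.nbd_oracle,
}
TOLERANCES = {"ipsen_mikhailov": 2e-4}


class TestOracleAgreement:
    """Each measure equals its independent brute-force oracle on small
    labeled digraphs: exhaustively on all pairs of 2-node digraphs, and on
    seeded random 3/4-node pairs."""

    @pytest.mark.parametrize("name", sorted(MEASURES))
    def test_all_two_node_pairs(self, name):
        graphs = [
            _oracles.adjacency(2, edges) for edges in _oracles.all_digraphs(2)
        ]
        for a1, a2 in itertools.combinations_with_replacement(graphs, 2):
            got = MEASURES[name](pair_from_matrices(a1, a2))
            want = ORACLES[name](a1, a2)
            assert got == pytest.approx(want, abs=TOLERANCES.get(name, 1e-9))

    @pytest.mark.parametrize("name", sorted(MEASURES))
    def test_random_small_pairs(self, name):
        rng = np.random.default_rng(31)
        n_pairs = 12 if name == "ipsen_mikhailov" else 40
        for _ in range(n_pairs):
            n = int(rng.integers(3, 5))
            mats = []
            for _ in range(2):
                a = (rng.random((n, n)) < rng.uniform(0.2, 0.7)).astype(float)
                a *= rng.integers(1, 5, size=(n, n))
                mats.append(a)
            got = MEASURES[name](pair_from_matrices(*mats))
            want = ORACLES[name](*mats)
            assert got == pytest.approx(want, abs=TOLERANCES.get(name, 1e-8))


class TestDistanceMatrix:
    def test_identical_graphs_zero_matrix(self):
        g = make_transition_graph([("A", "B", 1)], name="g1")
        dm = pairwise_distance_matrix([g, g.copy()], measure="frobenius")
        assert np.all(dm.values == 0)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(3)
        graphs = [
            random_transition_graph(rng, name=f"net{i}.csv") for i in range(4)
        ]
        dm = pairwise_distance_matrix(graphs, measure="portrait")
        assert np.array_equal(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)
        assert np.all(dm.values >= 0)

    def test_three_graphs_three_unique_offdiagonals(self):
        graphs = [
            make_transition_graph([("A", "B", 1)], name="aa"),
            make_transition_graph([("A", "B", 2), ("B", "A", 1)], name="bb"),
            make_transition_graph([("C", "D", 5)], name="cc"),
        ]
        dm = pairwise_distance_matrix(graphs, measure="frobenius")
        assert dm.values.shape == (3, 3)
        upper = dm.values[np.triu_indices(3, k=1)]
        assert len(upper) == 3

    def test_requires_two_graphs(self):
        with pytest.raises(ValueError):
            pairwise_distance_matrix(
                [make_transition_graph([("A", "B", 1)])], measure="frobenius"
            )

    def test_labels_first_two_chars_enumerated(self):
        assert network_labels(["Nm1.csv", "Nm2.csv", "Lo1.csv"]) == [
            "Nm1",
            "Nm2",
            "Lo",
        ]
        assert network_labels(["ab.csv", "cd.csv"]) == ["ab", "cd"]


class TestMDS:
    def dm(self):
        rng = np.random.default_rng(1)
        graphs = [random_transition_graph(rng, name=f"n{i}") for i in range(6)]
        return pairwise_distance_matrix(graphs, measure="portrait")

    def test_bitwise_reproducible(self):
        dm = self.dm()
        e1 = mds_embed(dm, n_init=4, seed=9)
        e2 = mds_embed(dm, n_init=4, seed=9)
        assert np.array_equal(e1.coordinates, e2.coordinates)
        assert e1.stress == e2.stress

    def test_nested_restarts_never_increase_stress(self):
        dm = self.dm()
        stresses = [mds_embed(dm, n_init=k, seed=1).stress for k in (1, 4, 16, 64)]
        assert all(a >= b - 1e-15 for a, b in zip(stresses, stresses[1:]))

    def test_agrees_with_sklearn_on_embeddable_input(self):
        # a distance matrix that is exactly realizable in the plane: both
        # our SMACOF and scikit-learn's must recover it (near-zero stress)
        from sklearn.manifold import MDS as SkMDS
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(6)
        pts = rng.random((6, 2)) * 3
        d = squareform(pdist(pts))
        dm = DistanceMatrix(labels=[f"p{i}" for i in range(6)], values=d)
        ours = mds_embed(dm, n_init=8, seed=0, max_iter=2000, tol=1e-14)
        ours_d = squareform(pdist(ours.coordinates))
        assert np.abs(ours_d - d).max() < 1e-4
        sk = SkMDS(
            n_components=2,
            dissimilarity="precomputed",
            n_init=8,
            random_state=0,
            normalized_stress=False,
        ).fit(d)
        sk_d = squareform(pdist(sk.embedding_))
        assert np.abs(sk_d - ours_d).max() < 1e-2

    def test_equilateral_triangle_embeds_perfectly(self):
        dm = DistanceMatrix(
            labels=["a", "b", "c"],
            values=np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float),
        )
        e = mds_embed(dm, n_init=8, seed=0, max_iter=2000, tol=1e-14)
        xy = e.coordinates
        dists = [
            np.linalg.norm(xy[i] - xy[j]) for i, j in [(0, 1), (0, 2), (1, 2)]
        ]
        assert max(dists) - min(dists) < 1e-6
        assert e.stress < 1e-10


class TestClustering:
    D = DistanceMatrix(
        labels=["x", "y", "z"],
        values=np.array([[0, 1, 4], [1, 0, 6], [4, 6, 0]], dtype=float),
    )

    def test_single_linkage(self):
        tree = hierarchical_clustering(self.D, linkage="single")
        assert [h for *_, h, _ in tree.merges] == [1.0, 4.0]

    def test_complete_linkage(self):
        tree = hierarchical_clustering(self.D, linkage="complete")
        assert [h for *_, h, _ in tree.merges] == [1.0, 6.0]

    def test_average_linkage(self):
        tree = hierarchical_clustering(self.D, linkage="average")
        assert [h for *_, h, _ in tree.merges] == [1.0, 5.0]

    def test_color_groups_strictly_below_threshold(self):
        tree = hierarchical_clustering(
            self.D, linkage="average", color_threshold=5.0
        )
        assert tree.color_groups() == [frozenset({"x", "y"}), frozenset({"z"})]
        all_merged = hierarchical_clustering(
            self.D, linkage="average", color_threshold=5.1
        )
        assert all_merged.color_groups() == [frozenset({"x", "y", "z"})]

    def test_heights_nondecreasing_all_linkages(self):
        rng = np.random.default_rng(8)
        pts = rng.random((7, 3))
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(
            labels=[f"p{i}" for i in range(7)],
            values=squareform(pdist(pts)),
        )
        for linkage in ("average", "complete", "single"):
            heights = hierarchical_clustering(dm, linkage=linkage).heights
            assert np.all(np.diff(heights) >= -1e-12)
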