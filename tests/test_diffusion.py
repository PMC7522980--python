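import numpy as np
import pytest
from scipy.spatial.distance import cdist

from nichemap import DiffusionMap, TraitMatrix
from nichemap.diffusion import (
    DiffusionConfig,
    NeighborGraph,
    diffusion_distance,
    diffusion_eigs,
    extremal_taxa,
    knn_graph,
    localization_score,
    row_normalized_laplacian,
)
from nichemap.synthetic import ClusterSpec, make_clustered_traits


def tiny_matrix():
    return TraitMatrix(
        ["g1", "g2", "g3"], ["a->x", "b->x"], [[1, 0], [1, 1], [0, 1]]
    )


class TestKnnGraph:
    def test_hand_example_with_tie(self):
        # d(g1,g2)=1, d(g2,g3)=1, d(g1,g3)=sqrt(2); g2's nearest is the
        # tie {g1,g3}, broken by input order -> g1; union symmetrization
        # leaves edges g1-g2 and g2-g3 with weight 1/d = 1.
        G = knn_graph(tiny_matrix(), DiffusionConfig(k=1, n_variables=1))
        expected = np.array([[0.0, 1, 0], [1, 0, 1], [0, 1, 0]])
        assert np.allclose(G.weights, expected)

    def test_symmetric_zero_diagonal(self, two_cluster_fixture):
        T, _ = two_cluster_fixture
        G = knn_graph(T, DiffusionConfig(k=5, n_variables=2))
        assert np.array_equal(G.weights, G.weights.T)
        assert np.all(np.diag(G.weights) == 0)
        # union symmetrization: every node keeps >= k positive weights
        assert (np.count_nonzero(G.weights, axis=1) >= 5).all()

    def test_duplicate_rows_rejected(self):
        T = TraitMatrix(
            ["g1", "g2", "g3"], ["a->x", "b->x"], [[1, 0], [1, 0], [0, 1]]
        )
        with pytest.raises(ValueError, match="duplicate"):
            knn_graph(T, DiffusionConfig(k=1, n_variables=1))

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="k="):
            knn_graph(tiny_matrix(), DiffusionConfig(k=3, n_variables=1))

    def test_gaussian_weights_bounded(self, two_cluster_fixture):
        T, _ = two_cluster_fixture
        G = knn_graph(
            T, DiffusionConfig(k=5, n_variables=2, weight_mode="gaussian")
        )
        w = G.weights[G.weights > 0]
        assert np.all((w > 0) & (w <= 1))


class TestLaplacian:
    def test_two_node_closed_form(self):
        G = NeighborGraph(["a", "b"], np.array([[0.0, 1], [1, 0]]))
        L = row_normalized_laplacian(G)
        assert np.allclose(L, [[1, -1], [-1, 1]])
        assert np.allclose(sorted(np.linalg.eigvals(L).real), [0, 2])

    def test_path_closed_form(self, path3_graph):
        L = row_normalized_laplacian(path3_graph)
        assert np.allclose(L, [[1, -1, 0], [-0.5, 1, -0.5], [0, -1, 1]])
        assert np.allclose(sorted(np.linalg.eigvals(L).real), [0, 1, 2])

    def test_rows_sum_to_zero(self, two_cluster_fixture):
        T, _ = two_cluster_fixture
        G = knn_graph(T, DiffusionConfig(k=5, n_variables=2))
        L = row_normalized_laplacian(G)
        assert np.abs(L.sum(axis=1)).max() < 1e-12

    def test_isolated_node_rejected(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        with pytest.raises(ValueError, match="isolated"):
            row_normalized_laplacian(NeighborGraph(["a", "b", "c"], W))


class TestDiffusionEigs:
    def test_path_graph_endpoints_at_extremes(self, path3_graph):
        R = diffusion_eigs(path3_graph, DiffusionConfig(k=1, n_variables=1))
        assert abs(R.eigenvalues[0]) < 1e-8
        assert np.isclose(R.eigenvalues[1], 1.0)
        v = R.variable(1)
        expected = np.array([1, 0, -1]) / np.sqrt(2)
        assert np.allclose(np.abs(v), np.abs(expected), atol=1e-8)
        assert np.isclose(v[0], -v[2])  # endpoints at opposite extremes

    def test_disconnected_graph_rejected(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = W[2, 3] = W[3, 2] = 1.0
        G = NeighborGraph(list("abcd"), W)
        with pytest.raises(ValueError, match="disconnected"):
            diffusion_eigs(G, DiffusionConfig(k=1, n_variables=1))
        # opt-in keeps the component indicator instead
        R = diffusion_eigs(
            G, DiffusionConfig(k=1, n_variables=1, allow_disconnected=True)
        )
        assert R.eigenvalues[1] < 1e-8

    def test_spectral_contract(self, two_cluster_fixture):
        T, _ = two_cluster_fixture
        config = DiffusionConfig(k=5, n_variables=6)
        G = knn_graph(T, config)
        R = diffusion_eigs(G, config)
        L = row_normalized_laplacian(G)
        assert np.all(np.diff(R.eigenvalues) >= -1e-12)
        assert np.all(R.eigenvalues >= -1e-8)
        assert np.all(R.eigenvalues <= 2 + 1e-8)
        for l in range(1, R.n_variables + 1):
            v, lam = R.variable(l), R.eigenvalues[l]
            resid = np.abs(L @ v - lam * v).max()
            assert resid < 1e-8 * max(np.abs(v).max(), 1.0)
            assert np.isclose(np.linalg.norm(v), 1.0)
            assert v[np.argmax(np.abs(v))] < 0  # sign convention

    def test_n_variables_bound(self, path3_graph):
        with pytest.raises(ValueError, match="n_variables"):
            diffusion_eigs(path3_graph, DiffusionConfig(k=1, n_variables=2))

    def test_determinism(self, two_cluster_fixture):
        T, _ = two_cluster_fixture
        a = DiffusionMap(k=5, n_variables=4).fit_transform(T)
        b = DiffusionMap(k=5, n_variables=4).fit_transform(T)
        assert np.array_equal(a, b)


class TestLocalization:
    def test_delta_vector(self):
        v = np.zeros(10)
        v[0] = 1.0
        assert localization_score(v) == 1.0

    def test_flat_vector_closed_form(self):
        assert np.isclose(localization_score(np.full(4, 0.5)), 0.25)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            localization_score(np.zeros(5))

    def test_planted_cluster_variable_is_localized(self):
        # a lone small cluster's separating variable concentrates weight
        spec = ClusterSpec(
            n_core_traits=40, clusters=[(5, 30)], n_background_genomes=25,
            flip_prob=0.05, seed=0,
        )
        T, labels = make_clustered_traits(spec)
        dm = DiffusionMap(k=5, n_variables=10).fit(T)
        sep = next(
            l for l in range(10)
            if (v := dm.embedding_[:, l])[labels == 0].max()
            < v[labels != 0].min()
            or v[labels == 0].min() > v[labels != 0].max()
        )
        assert dm.localization_[sep] >= np.median(dm.localization_[sep + 1:])


class TestDiffusionDistance:
    def test_flat_equals_brute_force(self, two_cluster_fixture):
        T, _ = two_cluster_fixture
        dm = DiffusionMap(k=5, n_variables=4).fit(T)
        D = diffusion_distance(dm.result_)
        brute = cdist(dm.embedding_, dm.embedding_)
        assert np.allclose(D, brute)
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)

    def test_single_variable_example(self, path3_graph):
        R = diffusion_eigs(path3_graph, DiffusionConfig(k=1, n_variables=1))
        D = diffusion_distance(R)
        v = R.variable(1)
        assert np.isclose(D[0, 2], abs(v[0] - v[2]))

    def test_inverse_eigenvalue_rescales(self, two_cluster_fixture):
        T, _ = two_cluster_fixture
        dm = DiffusionMap(k=5, n_variables=3).fit(T)
        D = diffusion_distance(dm.result_, "inverse_eigenvalue")
        scaled = dm.embedding_ / dm.eigenvalues_[1:]
        assert np.allclose(D, cdist(scaled, scaled))


class TestExtremalTaxa:
    @staticmethod
    def result_with(entries, ids=None):
        from nichemap.diffusion import DiffusionResult

        v = np.asarray(entries, float)
        ids = ids or [f"g{i+1}" for i in range(len(v))]
        return DiffusionResult(
            ids, np.array([0.0, 0.5]), v[:, None], np.array([0.1])
        )

    def test_single_extremes(self):
        R = self.result_with([-0.9, -0.1, 0.0, 0.2, 0.8])
        neg, pos = extremal_taxa(R, 1, 1)
        assert (neg, pos) == (["g1"], ["g5"])

    def test_two_extremes_ordering(self):
        R = self.result_with([-0.9, -0.1, 0.0, 0.2, 0.8])
        neg, pos = extremal_taxa(R, 1, 2)
        assert neg == ["g1", "g2"]  # ascending entries
        assert pos == ["g5", "g4"]  # descending entries

    def test_tie_broken_lexicographically(self):
        R = self.result_with(
            [-0.9, -0.9, 0.0, 0.2, 0.8], ids=["g2", "g1", "g3", "g4", "g5"]
        )
        neg, _ = extremal_taxa(R, 1, 2)
        assert neg == ["g1", "g2"]

    def test_n_too_large(self):
        R = self.result_with([-0.9, -0.1, 0.0, 0.2, 0.8])
        with pytest.raises(ValueError, match="N/2"):
            extremal_taxa(R, 1, 3)


class TestClusterRecovery:
    def test_variable_separates_planted_clusters(self, two_cluster_fixture):
        T, labels = two_cluster_fixture
        dm = DiffusionMap(k=10, n_variables=3).fit(T)
        assert self._separating_variable(dm, labels) is not None

    @staticmethod
    def _separating_variable(dm, labels):
        for l in range(dm.embedding_.shape[1]):
            v = dm.embedding_[:, l]
            for c in (0, 1):
                inside, outside = v[labels == c], v[labels != c]
                if inside.max() < outside.min() or inside.min() > outside.max():
                    return l
        return None

    def test_k_robustness(self, two_cluster_fixture):
        # the variable-1 split of the planted cluster members is the same
        # for k in {5, 10, 15} (up to the arbitrary global sign)
        T, labels = two_cluster_fixture
        members = labels >= 0
        assignments = []
        for k in (5, 10, 15):
            v = DiffusionMap(k=k, n_variables=1).fit(T).embedding_[:, 0]
            side = v[members] > 0
            assignments.append(side if side[0] else ~side)
        assert np.array_equal(assignments[0], assignments[1])
        assert np.array_equal(assignments[1], assignments[2])
        # and the split is exactly the planted two-cluster labeling
        truth = labels[members] == labels[members][0]
        assert np.array_equal(assignments[0], truth)

    def test_localized_variable_beats_unstructured_control(self):
        spec = ClusterSpec(
            n_core_traits=40, clusters=[(5, 30)], n_background_genomes=25,
            flip_prob=0.05, seed=0,
        )
        T, _ = make_clustered_traits(spec)
        # matched control: same size, pure Bernoulli noise, no structure
        control_spec = ClusterSpec(
            n_core_traits=40, clusters=[(2, 0)], n_background_genomes=28,
            flip_prob=0.25, seed=0,
        )
        Tc, _ = make_clustered_traits(control_spec)
        ipr_planted = DiffusionMap(k=5, n_variables=5).fit(T).localization_[0]
        ipr_control = DiffusionMap(k=5, n_variables=5).fit(Tc).localization_
        assert ipr_planted > ipr_control.max()


def test_sklearn_estimator_api(two_cluster_fixture):
    T, _ = two_cluster_fixture
    dm = DiffusionMap()
    params = dm.get_params()
    assert params["k"] == 10 and params["weight_mode"] == "inverse_distance"
    dm.set_params(k=5, n_variables=2)
    coords = dm.fit_transform(T)
    assert coords.shape == (len(T.genome_ids), 2)
    assert hasattr(dm, "eigenvalues_") and hasattr(dm, "embedding_")
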