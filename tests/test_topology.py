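"""Topology metrics: strength, Barrat clustering, hierarchy/scale-free
diagnostics, eigenvector centrality."""

import numpy as np
import pytest

from crnet import (
    CentralityProfile,
    GeneNetwork,
    ValidationError,
    eigenvector_centrality,
    generate_reference_networks,
    hierarchy_diagnostic,
    identify_central_genes,
    node_strength,
    scalefree_diagnostic,
    weighted_clustering,
)
from crnet.topology import fit_power_law
from conftest import random_weighted_network


def barrat_oracle(adj: np.ndarray) -> np.ndarray:
    """Triple-loop Barrat clustering coefficient."""
    n = adj.shape[0]
    a = adj > 0
    out = np.zeros(n)
    for i in range(n):
        k = a[i].sum()
        s = adj[i].sum()
        if k < 2:
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h and a[i, j] and a[i, h] and a[j, h]:
                    acc += (adj[i, j] + adj[i, h]) / 2
        out[i] = acc / (s * (k - 1))
    return out


class TestStrengthAndClustering:
    def test_triangle_strengths(self, triangle):
        assert np.allclose(node_strength(triangle), 2.0)

    def test_isolated_node_and_weighted_sum(self):
        adj = np.zeros((4, 4))
        adj[0, 1] = adj[1, 0] = 0.5
        adj[0, 2] = adj[2, 0] = 0.3
        net = GeneNetwork(list("abcd"), adj)
        s = node_strength(net)
        assert s[0] == pytest.approx(0.8) and s[3] == 0.0

    def test_triangle_clustering_is_one(self, triangle):
        assert np.allclose(weighted_clustering(triangle), 1.0)

    def test_star_center_clustering_zero(self):
        adj = np.zeros((4, 4))
        for j in (1, 2, 3):
            adj[0, j] = adj[j, 0] = 1.0
        assert weighted_clustering(GeneNetwork(list("abcd"), adj))[0] == 0.0

    def test_closed_unequal_weight_neighbourhood(self):
        # closed neighbourhood: Barrat coefficient is 1 regardless of weights
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 2.0
        adj[0, 2] = adj[2, 0] = 1.0
        adj[1, 2] = adj[2, 1] = 1.0
        assert weighted_clustering(GeneNetwork(list("ijh"), adj))[0] == pytest.approx(1.0)

    def test_matches_bruteforce_on_random_graphs(self):
        for s in range(10):
            net = random_weighted_network(15, seed=s)
            assert np.allclose(weighted_clustering(net), barrat_oracle(net.adjacency),
                               atol=1e-12)
            assert np.allclose(node_strength(net), net.adjacency.sum(axis=1),
                               atol=1e-12)

    def test_matches_igraph_barrat(self):
        igraph = pytest.importorskip("igraph")
        net = random_weighted_network(20, seed=3, connected=True)
        ii, jj = np.nonzero(np.triu(net.adjacency, 1))
        g = igraph.Graph(edges=list(zip(ii.tolist(), jj.tolist())), n=20)
        ref = g.transitivity_local_undirected(
            weights=net.adjacency[ii, jj].tolist(), mode="zero"
        )
        assert np.allclose(weighted_clustering(net), ref, atol=1e-10)


class TestHierarchyDiagnostic:
    def test_nested_clique_fixture_is_hierarchical(self):
        net = generate_reference_networks("nested_cliques", 125, 5)
        s, c = node_strength(net), weighted_clustering(net)
        rho, p, verdict = hierarchy_diagnostic(s, c, net.degrees())
        assert verdict is True and rho < 0

    def test_erdos_renyi_not_hierarchical(self):
        net = generate_reference_networks("random", 400, 12, seed=1)
        s, c = node_strength(net), weighted_clustering(net)
        _, _, verdict = hierarchy_diagnostic(s, c, net.degrees())
        assert verdict is False

    def test_degenerate_constant_clustering_inconclusive(self):
        s = np.linspace(1, 2, 20)
        c = np.full(20, 0.5)
        rho, p, verdict = hierarchy_diagnostic(s, c, np.full(20, 3))
        assert verdict is None

    def test_too_few_eligible_nodes_warns(self):
        with pytest.warns(UserWarning, match="inconclusive"):
            _, _, verdict = hierarchy_diagnostic(
                np.ones(5), np.ones(5), np.full(5, 2)
            )
        assert verdict is None


class TestScaleFreeDiagnostic:
    def test_pareto_ml_exponent_consistent(self):
        rng = np.random.default_rng(1)
        x = (1 - rng.random(1000)) ** (-1 / 1.5)  # Pareto alpha=2.5, xmin=1
        alpha, _, _ = fit_power_law(x)
        assert 2.3 <= alpha <= 2.7

    def test_preferential_attachment_judged_scale_free(self):
        yes = sum(
            scalefree_diagnostic(
                node_strength(generate_reference_networks("scale_free", 400, 2, seed=s)),
                seed=s,
            )["scale_free"]
            for s in range(10)
        )
        assert yes >= 8

    def test_uniform_strengths_not_scale_free(self):
        rng = np.random.default_rng(2)
        assert not scalefree_diagnostic(rng.uniform(1, 2, 400), seed=2)["scale_free"]

    def test_nonpositive_strengths_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([(1 - rng.random(500)) ** (-1 / 1.5), [0.0, -1.0]])
        with pytest.warns(UserWarning, match="non-positive"):
            d = scalefree_diagnostic(x, seed=3)
        assert "excluded 2 non-positive strengths" in d["notes"]

    def test_too_few_strengths_error(self):
        with pytest.raises(ValidationError):
            scalefree_diagnostic(np.ones(10), seed=0)


class TestEigenvectorCentrality:
    def test_path_graph_values(self, path_abc):
        prof = eigenvector_centrality(path_abc)
        assert np.allclose(prof.centrality, [0.7071, 1.0, 0.7071], atol=5e-5)

    def test_complete_graph_all_equal(self):
        adj = 0.7 * (np.ones((5, 5)) - np.eye(5))
        prof = eigenvector_centrality(GeneNetwork([f"g{i}" for i in range(5)], adj))
        assert np.allclose(prof.centrality, 1.0)

    def test_matches_power_iteration_oracle(self):
        for s in range(10):
            net = random_weighted_network(25, seed=100 + s, connected=True)
            prof = eigenvector_centrality(net)
            rng = np.random.default_rng(s)
            v = rng.random(25) + 0.1
            for _ in range(5000):
                nv = net.adjacency @ v
                nv /= np.linalg.norm(nv)
                if np.linalg.norm(nv - v) < 1e-14:
                    break
                v = nv
            assert np.allclose(prof.centrality, v / v.max(), atol=1e-8)

    def test_invariant_to_uniform_rescaling(self):
        net = random_weighted_network(15, seed=2, connected=True)
        scaled = GeneNetwork(net.nodes, net.adjacency * 7.3)
        a = eigenvector_centrality(net).centrality
        b = eigenvector_centrality(scaled).centrality
        assert np.allclose(a, b, atol=1e-10)

    def test_disconnected_graph_zeroes_minor_component(self, two_triangles):
        adj = two_triangles.adjacency.copy()
        adj[:3, :3] *= 2  # first triangle dominates
        with pytest.warns(UserWarning, match="disconnected"):
            prof = eigenvector_centrality(GeneNetwork(two_triangles.nodes, adj))
        assert np.allclose(prof.centrality[:3], 1.0)
        assert np.allclose(prof.centrality[3:], 0.0)

    def test_edgeless_network_errors(self):
        with pytest.raises(ValidationError, match="centrality undefined"):
            eigenvector_centrality(GeneNetwork(["a", "b"], np.zeros((2, 2))))


class TestCentralGenes:
    def test_threshold_selection(self):
        prof = CentralityProfile(["a", "b", "c"], np.array([1.0, 0.95, 0.3]), 2.0, [0, 1, 2])
        assert identify_central_genes(prof, 0.9) == ["a", "b"]
        assert identify_central_genes(prof, 1.0) == ["a"]

    def test_invalid_tau(self):
        prof = CentralityProfile(["a"], np.array([1.0]), 1.0, [0])
        with pytest.raises(ValidationError):
            identify_central_genes(prof, 0.0)
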