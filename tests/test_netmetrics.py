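"""Centralities, communities, node roles and small-world statistics."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cfosnet.netmetrics import (
    CONNECTOR_HUB,
    NONHUB_CONNECTOR,
    PERIPHERAL,
    PROVINCIAL_HUB,
    ROLES,
    CommunityPartition,
    UndefinedMetricError,
    avg_shortest_path,
    classify_roles,
    clustering_coefficient,
    degree_centrality,
    eigenvector_centrality,
    er_ensemble,
    louvain,
    node_metrics_table,
    participation_coefficient,
    small_worldness,
    within_module_zscore,
)
from conftest import (
    net_from_adjacency,
    oracle_avg_shortest_path,
    oracle_clustering,
    oracle_power_iteration,
    random_adjacency,
)


def star(n=5):
    adj = np.zeros((n, n), dtype=bool)
    adj[0, 1:] = adj[1:, 0] = True
    return adj


def two_triangles():
    adj = np.zeros((6, 6), dtype=bool)
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        adj[a, b] = adj[b, a] = True
    return adj


class TestCentralities:
    def test_star_degrees(self):
        deg = degree_centrality(net_from_adjacency(star()))
        assert deg["n0"] == 4 and (deg.drop("n0") == 1).all()

    def test_handshake_lemma(self, rng):
        adj = random_adjacency(30, 0.2, rng)
        net = net_from_adjacency(adj)
        assert degree_centrality(net).sum() == 2 * net.n_edges

    def test_degree_equals_adjacency_row_sums(self, rng):
        adj = random_adjacency(15, 0.3, rng)
        assert np.array_equal(
            degree_centrality(net_from_adjacency(adj)).to_numpy(), adj.sum(axis=1)
        )

    def test_cycle_eigenvector_uniform(self):
        adj = np.zeros((6, 6), dtype=bool)
        for i in range(6):
            adj[i, (i + 1) % 6] = adj[(i + 1) % 6, i] = True
        ev = eigenvector_centrality(net_from_adjacency(adj))
        assert np.allclose(ev, 1.0)

    def test_star_center_maximal(self):
        ev = eigenvector_centrality(net_from_adjacency(star()))
        assert ev.idxmax() == "n0" and ev["n0"] == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_power_iteration_oracle(self, seed):
        adj = random_adjacency(20, 0.25, np.random.default_rng(seed))
        if adj.sum() == 0:
            pytest.skip("edgeless draw")
        ev = eigenvector_centrality(net_from_adjacency(adj))
        assert np.allclose(ev.to_numpy(), oracle_power_iteration(adj), atol=1e-8)

    def test_edgeless_errors(self):
        with pytest.raises(UndefinedMetricError):
            eigenvector_centrality(net_from_adjacency(np.zeros((3, 3), bool)))


class TestLouvain:
    def test_disjoint_triangles_found_as_components(self):
        part = louvain(net_from_adjacency(two_triangles()), seed=0)
        assert part.n_communities == 2
        labels = part.labels_for([f"n{i}" for i in range(6)])
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(5)
        n_blocks, size = 4, 12
        n = n_blocks * size
        truth = np.repeat(np.arange(n_blocks), size)
        aris = []
        from sklearn.metrics import adjusted_rand_score

        for seed in range(5):
            r = np.random.default_rng(seed)
            same = truth[:, None] == truth[None, :]
            p = np.where(same, 0.7, 0.02)
            adj = np.triu(r.random((n, n)) < p, k=1)
            adj = adj | adj.T
            part = louvain(net_from_adjacency(adj), seed=seed)
            pred = part.labels_for([f"n{i}" for i in range(n)])
            aris.append(adjusted_rand_score(truth, pred))
        assert np.median(aris) >= 0.9

    def test_modularity_matches_direct_formula(self, rng):
        adj = random_adjacency(25, 0.15, rng)
        net = net_from_adjacency(adj)
        part = louvain(net, seed=3)
        # direct evaluation: Q = (1/2m) Σ_ij [A_ij − k_i k_j / 2m] δ(c_i, c_j)
        a = adj.astype(float)
        k = a.sum(axis=1)
        two_m = a.sum()
        labels = part.labels_for(net.region_ids)
        delta = labels[:, None] == labels[None, :]
        q = ((a - np.outer(k, k) / two_m) * delta).sum() / two_m
        assert part.modularity == pytest.approx(q, abs=1e-12)

    def test_modularity_beats_singletons(self, rng):
        adj = random_adjacency(20, 0.2, rng)
        net = net_from_adjacency(adj)
        part = louvain(net, seed=1)
        a = adj.astype(float)
        k = a.sum(axis=1)
        two_m = a.sum()
        q_singletons = (np.diag(a) - k**2 / two_m).sum() / two_m
        assert part.modularity >= q_singletons

    def test_contiguous_ids_enforced(self):
        with pytest.raises(ValueError):
            CommunityPartition(assignment={"a": 1, "b": 3}, modularity=0.0)


class TestNodeRoles:
    def make_partition(self, net, labels):
        return CommunityPartition(
            assignment=dict(zip(net.region_ids, labels)), modularity=0.0
        )

    def test_clique_community_all_zero_z(self):
        adj = two_triangles()
        net = net_from_adjacency(adj)
        part = self.make_partition(net, [1, 1, 1, 2, 2, 2])
        assert (within_module_zscore(net, part) == 0).all()

    def test_z_hand_computation(self):
        # community with within-degrees (4, 1, 1): mean 2, population sd sqrt(2)
        adj = np.zeros((7, 7), dtype=bool)
        # community 1: nodes 0..4; node 0 connected to 1,2,3,4; node 1-2 edge
        for a, b in [(0, 1), (0, 2), (0, 3), (0, 4)]:
            adj[a, b] = adj[b, a] = True
        net = net_from_adjacency(adj)
        part = self.make_partition(net, [1, 1, 1, 2, 2, 2, 2])
        # within community 1 degrees: node0 -> 2 (nodes 1, 2), node1 -> 1, node2 -> 1
        z = within_module_zscore(net, part)
        kappa = np.array([2.0, 1.0, 1.0])
        expect = (kappa - kappa.mean()) / kappa.std()
        assert np.allclose(z.iloc[:3], expect)

    def test_z_941_example(self):
        # explicit κ = (4, 1, 1): z = (1.4142, −0.7071, −0.7071)
        kappa = np.array([4.0, 1.0, 1.0])
        z = (kappa - kappa.mean()) / kappa.std()
        assert np.allclose(z, [np.sqrt(2), -1 / np.sqrt(2), -1 / np.sqrt(2)], atol=1e-4)

    def test_z_sums_to_zero_within_community(self, rng):
        adj = random_adjacency(24, 0.3, rng)
        net = net_from_adjacency(adj)
        labels = rng.integers(1, 4, size=24)
        labels[:3] = [1, 2, 3]  # ensure all ids appear
        part = self.make_partition(net, labels)
        z = within_module_zscore(net, part)
        for c in (1, 2, 3):
            members = z[labels == c]
            if members.std() > 0:
                assert members.sum() == pytest.approx(0, abs=1e-10)

    def test_participation_single_community_zero(self):
        net = net_from_adjacency(two_triangles())
        part = self.make_partition(net, [1, 1, 1, 2, 2, 2])
        p = participation_coefficient(net, part)
        assert (p == 0).all()

    def test_participation_even_split(self):
        # node 0 with 4 edges split 2/2 over two communities -> P = 0.5
        adj = np.zeros((5, 5), dtype=bool)
        adj[0, 1:] = adj[1:, 0] = True
        net = net_from_adjacency(adj)
        part = self.make_partition(net, [1, 1, 1, 2, 2])
        p = participation_coefficient(net, part)
        assert p["n0"] == pytest.approx(0.5)

    def test_participation_3_2_1_split(self):
        # degree-6 node split 3/2/1 -> 1 - (9+4+1)/36 = 0.6111...
        adj = np.zeros((7, 7), dtype=bool)
        adj[0, 1:] = adj[1:, 0] = True
        net = net_from_adjacency(adj)
        part = self.make_partition(net, [1, 1, 1, 1, 2, 2, 3])
        p = participation_coefficient(net, part)
        assert p["n0"] == pytest.approx(1 - 14 / 36)

    def test_participation_bound(self, rng):
        adj = random_adjacency(30, 0.3, rng)
        net = net_from_adjacency(adj)
        labels = rng.integers(1, 5, size=30)
        labels[:4] = [1, 2, 3, 4]
        part = self.make_partition(net, labels)
        p = participation_coefficient(net, part)
        assert (p <= 1 - 1 / part.n_communities + 1e-12).all()
        assert (p >= 0).all()

    def test_role_quadrants(self):
        z = pd.Series([3.0, 3.0, 0.0, 0.0], index=list("abcd"))
        p = pd.Series([0.1, 0.5, 0.7, 0.1], index=list("abcd"))
        roles = classify_roles(z, p)
        assert list(roles) == [PROVINCIAL_HUB, CONNECTOR_HUB, NONHUB_CONNECTOR, PERIPHERAL]

    def test_roles_partition_exhaustively(self, rng):
        z = pd.Series(rng.normal(size=200) * 3)
        p = pd.Series(rng.random(200))
        roles = classify_roles(z, p)
        assert roles.isin(ROLES).all()

    def test_metrics_table_shape(self, rng):
        adj = random_adjacency(20, 0.25, rng)
        net = net_from_adjacency(adj)
        part = louvain(net, seed=0)
        table = node_metrics_table(net, part)
        assert list(table.columns) == [
            "degree", "eigenvector", "community", "z_within", "participation", "role",
        ]
        assert len(table) == 20


class TestPathAndClustering:
    def test_triangle_values(self):
        adj = two_triangles()[:3, :3]
        net = net_from_adjacency(adj)
        assert avg_shortest_path(net) == pytest.approx(1.0)
        assert clustering_coefficient(net) == pytest.approx(1.0)

    def test_path_graph(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)
        assert avg_shortest_path(net_from_adjacency(adj)) == pytest.approx(4 / 3)

    def test_disconnected_pairs_excluded(self):
        adj = np.zeros((4, 4), dtype=bool)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = True
        assert avg_shortest_path(net_from_adjacency(adj)) == pytest.approx(1.0)

    def test_no_pairs_errors(self):
        with pytest.raises(UndefinedMetricError):
            avg_shortest_path(net_from_adjacency(np.zeros((3, 3), bool)))

    def test_star_clustering_zero(self):
        # center has degree >= 2 with unconnected neighbours -> 0; leaves excluded
        assert clustering_coefficient(net_from_adjacency(star())) == 0.0

    def test_all_low_degree_errors_or_zero_fills(self):
        adj = np.zeros((4, 4), dtype=bool)
        adj[0, 1] = adj[1, 0] = True
        with pytest.raises(UndefinedMetricError):
            clustering_coefficient(net_from_adjacency(adj))
        assert clustering_coefficient(net_from_adjacency(adj), low_degree="zero") == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_match_bfs_and_triangle_oracles(self, seed):
        adj = random_adjacency(10, 0.35, np.random.default_rng(seed))
        net = net_from_adjacency(adj)
        assert avg_shortest_path(net) == pytest.approx(oracle_avg_shortest_path(adj))
        assert clustering_coefficient(net) == pytest.approx(oracle_clustering(adj))

    def test_nx_cross_check(self, rng):
        adj = random_adjacency(15, 0.3, rng)
        net = net_from_adjacency(adj)
        g = net.to_networkx()
        deg_ok = [v for v in g if g.degree(v) >= 2]
        assert clustering_coefficient(net) == pytest.approx(
            np.mean([nx.clustering(g, v) for v in deg_ok])
        )


class TestERandSmallWorld:
    def test_complete_graph_limits(self):
        st = er_ensemble(8, 28, n_rep=5, seed=0)
        assert st.l_rand == pytest.approx(1.0)
        assert st.c_rand == pytest.approx(1.0)

    def test_seed_determinism(self):
        a = er_ensemble(30, 60, n_rep=20, seed=7)
        b = er_ensemble(30, 60, n_rep=20, seed=7)
        assert (a.l_rand, a.c_rand) == (b.l_rand, b.c_rand)

    def test_sparse_er_matches_analytic_approximation(self):
        # L ≈ ln(n)/ln(2m/n) for ER graphs
        st = er_ensemble(143, 256, n_rep=100, seed=3)
        approx = np.log(143) / np.log(2 * 256 / 143)
        assert st.l_rand == pytest.approx(approx, abs=0.5)

    def test_edge_count_bounds(self):
        with pytest.raises(ValueError):
            er_ensemble(5, 11, n_rep=2, seed=0)

    def test_sigma_worked_example(self):
        assert round(small_worldness(5.6, 0.38, 3.9, 0.024), 1) == 11.0

    def test_sigma_identity_and_linearity(self):
        assert small_worldness(2.0, 0.3, 2.0, 0.3) == pytest.approx(1.0)
        s1 = small_worldness(3.0, 0.2, 2.5, 0.05)
        s2 = small_worldness(3.0, 0.4, 2.5, 0.05)
        assert s2 == pytest.approx(2 * s1)

    def test_sigma_domain_errors(self):
        with pytest.raises(ValueError):
            small_worldness(0.0, 0.3, 2.0, 0.1)
        with pytest.raises(ValueError):
            small_worldness(2.0, 0.3, 2.0, -0.1)
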