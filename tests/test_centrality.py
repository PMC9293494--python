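"""Six centrality metrics against closed forms and independent oracles,
and the above-mean key-target screen."""

import math

import numpy as np
import pytest

from helpers import (
    betweenness_oracle,
    closeness_oracle,
    eigenvector_oracle,
    key_node_rule_oracle,
    lac_oracle,
    nc_oracle,
    random_graph,
)
from conftest import complete_graph

from herbnetpharm.centrality import (
    METRICS,
    betweenness_centrality,
    centrality_table,
    closeness_centrality,
    degree_centrality,
    eigenvector_centrality,
    local_average_connectivity,
    network_centrality,
    screen_key_nodes,
)
from herbnetpharm.errors import ValidationError
from herbnetpharm.graph import InteractionGraph


class TestClosedForms:
    def test_degree_star(self, star4):
        dc = degree_centrality(star4)
        assert dc["hub"] == 4 and all(dc[f"L{i}"] == 1 for i in range(4))

    def test_degree_isolated(self):
        g = InteractionGraph(nodes=["A", "B"], edges=[])
        assert degree_centrality(g) == {"A": 0.0, "B": 0.0}

    def test_closeness_complete(self, k4):
        assert all(v == 1.0 for v in closeness_centrality(k4).values())

    def test_closeness_path(self, path3):
        cc = closeness_centrality(path3)
        assert cc["B"] == 1.0
        assert cc["A"] == pytest.approx(2 / 3) and cc["C"] == pytest.approx(2 / 3)

    def test_betweenness_path(self, path3):
        bc = betweenness_centrality(path3)
        assert bc == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_betweenness_star(self, star4):
        bc = betweenness_centrality(star4)
        assert bc["hub"] == 6.0  # C(4, 2) transit pairs
        assert all(bc[f"L{i}"] == 0.0 for i in range(4))

    def test_eigenvector_complete(self, k4):
        ec = eigenvector_centrality(k4)
        assert all(v == pytest.approx(0.5, abs=1e-8) for v in ec.values())

    def test_eigenvector_path(self, path3):
        ec = eigenvector_centrality(path3)
        assert ec["B"] == pytest.approx(math.sqrt(2) / 2, abs=1e-8)
        assert ec["A"] == pytest.approx(0.5, abs=1e-8)

    def test_eigenvector_needs_edges(self):
        with pytest.raises(ValidationError):
            eigenvector_centrality(InteractionGraph(nodes=["A"]))

    def test_lac_triangle_star_k4(self, triangle, star4, k4):
        assert all(v == 1.0 for v in local_average_connectivity(triangle).values())
        assert local_average_connectivity(star4)["hub"] == 0.0
        assert all(v == 2.0 for v in local_average_connectivity(k4).values())

    def test_nc_triangle_star_k4(self, triangle, star4, k4):
        assert all(v == 2.0 for v in network_centrality(triangle).values())
        assert all(v == 0.0 for v in network_centrality(star4).values())
        assert all(v == 3.0 for v in network_centrality(k4).values())

    def test_table_means_triangle(self, triangle):
        table = centrality_table(triangle)
        expected = {"dc": 2.0, "cc": 1.0, "bc": 0.0, "lac": 1.0, "nc": 2.0,
                    "ec": 1 / math.sqrt(3)}
        for metric, value in expected.items():
            assert table.means[metric] == pytest.approx(value, abs=1e-8)

    def test_table_means_star(self, star4):
        table = centrality_table(star4)
        assert table.means["dc"] == pytest.approx(8 / 5)
        assert table.means["bc"] == pytest.approx(6 / 5)

    def test_ec_column_is_l2_normalized(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            table = centrality_table(random_graph(rng))
            assert np.linalg.norm(table.values["ec"]) == pytest.approx(1.0, abs=1e-6)
            assert np.isfinite(table.values.to_numpy()).all()


N_ORACLE_GRAPHS = 60


@pytest.fixture(scope="module")
def graphs():
    rng = np.random.default_rng(20260926)
    return [random_graph(rng, n_max=8) for _ in range(N_ORACLE_GRAPHS)]


@pytest.fixture(scope="module")
def connected_graphs():
    rng = np.random.default_rng(4111)
    return [random_graph(rng, n_max=8, connected=True) for _ in range(N_ORACLE_GRAPHS)]


class TestOracles:
    """Each metric equals its independent oracle on many small graphs."""

    def test_closeness_matches_floyd_warshall(self, graphs):
        for g in graphs:
            oracle = closeness_oracle(g)
            for v, val in closeness_centrality(g).items():
                assert val == pytest.approx(oracle[v], abs=1e-12)

    def test_betweenness_matches_path_enumeration(self, graphs):
        for g in graphs:
            oracle = betweenness_oracle(g)
            for v, val in betweenness_centrality(g).items():
                assert val == pytest.approx(oracle[v], abs=1e-9)

    def test_eigenvector_matches_dense_eigensolver(self, connected_graphs):
        for g in connected_graphs:
            oracle = eigenvector_oracle(g)
            for v, val in eigenvector_centrality(g).items():
                assert val == pytest.approx(oracle[v], abs=1e-8)

    def test_lac_matches_neighbourhood_recount(self, graphs):
        for g in graphs:
            oracle = lac_oracle(g)
            for v, val in local_average_connectivity(g).items():
                assert val == pytest.approx(oracle[v], abs=1e-12)

    def test_nc_matches_common_neighbour_recount(self, graphs):
        for g in graphs:
            oracle = nc_oracle(g)
            for v, val in network_centrality(g).items():
                assert val == pytest.approx(oracle[v], abs=1e-12)

    def test_metrics_invariant_under_relabeling(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            g = random_graph(rng, n_max=8)
            perm = {n: f"x{i}" for i, n in enumerate(rng.permutation(g.nodes))}
            h = InteractionGraph(
                nodes=[perm[n] for n in g.nodes],
                edges=[(perm[u], perm[v]) for u, v in g.edges()],
            )
            tg, th = centrality_table(g), centrality_table(h)
            for metric in METRICS:
                for n in g.nodes:
                    assert tg.values.at[n, metric] == pytest.approx(
                        th.values.at[perm[n], metric], abs=1e-7
                    )


class TestScreen:
    def test_complete_graph_yields_empty_key_set(self, k5):
        table = centrality_table(k5)
        assert screen_key_nodes(table, k5, strict=True).key_nodes == []

    def test_star_yields_empty_key_set(self, star4):
        # every LAC is 0, so not even the hub strictly exceeds the LAC mean
        table = centrality_table(star4)
        assert screen_key_nodes(table, star4, strict=True).key_nodes == []

    def test_non_strict_complete_graph_keeps_everything(self, k5):
        table = centrality_table(k5)
        assert set(screen_key_nodes(table, k5, strict=False).key_nodes) == set(k5.nodes)

    def test_matches_independent_rule_oracle(self):
        rng = np.random.default_rng(777)
        for _ in range(50):
            g = random_graph(rng, n_max=8)
            table = centrality_table(g)
            ours = set(screen_key_nodes(table, g, strict=True).key_nodes)
            assert ours == key_node_rule_oracle(g, strict=True)

    def test_central_network_is_induced_subgraph(self):
        rng = np.random.default_rng(97)
        for _ in range(20):
            g = random_graph(rng, n_max=10)
            res = screen_key_nodes(centrality_table(g), g)
            assert set(res.central.nodes) <= set(g.nodes)
            assert res.central.edge_set() <= g.edge_set()
            # induced: every parent edge between key nodes is present
            keys = set(res.key_nodes)
            expected = {(u, v) for u, v in g.edges() if u in keys and v in keys}
            assert res.central.edge_set() == expected

    def test_screen_invariant_to_per_metric_rescaling(self):
        # only comparisons to the mean are used, so scaling any metric
        # column cannot change the key set
        rng = np.random.default_rng(55)
        g = random_graph(rng, n_max=10)
        table = centrality_table(g)
        scaled = centrality_table(g)
        scaled.values["bc"] *= 7.0
        scaled.values["dc"] *= 0.01
        scaled.means = scaled.values.mean(axis=0)
        assert (
            screen_key_nodes(table, g).key_nodes
            == screen_key_nodes(scaled, g).key_nodes
        )

    def test_key_nodes_sorted_by_degree_then_id(self):
        g = complete_graph(4)
        g.add_edge("A", "E")  # A now strictly dominates
        table = centrality_table(g)
        res = screen_key_nodes(table, g, strict=False)
        degrees = [g.degree(n) for n in res.key_nodes]
        assert degrees == sorted(degrees, reverse=True)
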