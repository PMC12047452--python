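"""Transition matrix, damped rank iteration, and fixed-point checks."""

import numpy as np
import pytest

from stpath.keyfactors import RankConfig, node_rank, rank_nodes, transition_matrix
from stpath.network import build_network
from stpath.pathway_io import Interaction, Pathway
from stpath.st_core import parse_st_code
from stpath.synth import SynthConfig, generate_catalog, generate_pathways

CODE = parse_st_code("4.1.1.1")


def edge_net(*edges, scheme="unit"):
    """Network from (source, target) pairs, or (source, target, weight)
    realized as that many parallel pathways."""
    pathways = []
    k = 0
    for e in edges:
        s, t, w = (e if len(e) == 3 else (*e, 1))
        for _ in range(int(w)):
            k += 1
            pathways.append(Pathway(f"p{k}", (Interaction(s, t, CODE),)))
    return build_network(pathways, "multiplicity" if scheme == "multiplicity" else "unit")


def cycle_net(n):
    steps = tuple(
        Interaction(f"N{i:02d}", f"N{(i + 1) % n:02d}", CODE) for i in range(n)
    )
    return build_network([Pathway("cyc", steps)], "unit")


@pytest.fixture(scope="module")
def fixture_net():
    cfg = SynthConfig(seed=3, n_entities=60, n_interactions=240, n_pathways=40,
                      length_range=(3, 8))
    return build_network(generate_pathways(generate_catalog(cfg), cfg))


class TestTransitionMatrix:
    def test_two_cycle(self):
        M, nodes = transition_matrix(edge_net(("A", "B"), ("B", "A")))
        assert nodes == ["A", "B"]
        assert M.tolist() == [[0.0, 1.0], [1.0, 0.0]]

    def test_star_in_weights(self):
        M, nodes = transition_matrix(edge_net(("A", "D"), ("B", "D"), ("C", "D")))
        d_row = M[nodes.index("D")]
        np.testing.assert_allclose(d_row[:3], [1 / 3, 1 / 3, 1 / 3])
        assert M[:3].sum() == 0.0  # A, B, C have no in-edges

    def test_weighted_in_normalization(self):
        net = build_network(
            [Pathway(f"p{i}", (Interaction("A", "C", CODE),)) for i in range(3)]
            + [Pathway("q", (Interaction("B", "C", CODE),))],
            "multiplicity",
        )
        M, nodes = transition_matrix(net)
        c = nodes.index("C")
        assert M[c, nodes.index("A")] == 0.75
        assert M[c, nodes.index("B")] == 0.25

    def test_out_weights_columns_stochastic(self, fixture_net):
        M, nodes = transition_matrix(fixture_net, "out_weights")
        col_sums = M.sum(axis=0)
        for j, s in enumerate(col_sums):
            assert s == pytest.approx(1.0, abs=1e-12) or s == 0.0

    def test_in_weights_rows_stochastic(self, fixture_net):
        M, _ = transition_matrix(fixture_net, "in_weights")
        for s in M.sum(axis=1):
            assert s == pytest.approx(1.0, abs=1e-12) or s == 0.0


class TestNodeRank:
    @pytest.mark.parametrize("n", [2, 5, 17])
    def test_cycle_uniform_fixed_point(self, n):
        res = node_rank(cycle_net(n))
        for v in res.values.values():
            assert v == pytest.approx(1.0 / n, abs=1e-9)

    def test_source_node_sits_at_teleport_floor(self):
        res = node_rank(edge_net(("A", "B")))
        assert res.values["A"] == pytest.approx(0.15 / 2, abs=1e-15)

    def test_star_matches_directly_solved_linear_system(self):
        """Oracle: solve (I - dM) R = (1-d)/n directly for the 4-node star."""
        net = edge_net(("A", "D"), ("B", "D"), ("C", "D"))
        M, nodes = transition_matrix(net)
        n = len(nodes)
        expected = np.linalg.solve(np.eye(n) - 0.85 * M, np.full(n, 0.15 / n))
        res = node_rank(net)
        np.testing.assert_allclose([res.values[v] for v in nodes], expected, atol=1e-8)
        assert res.values["D"] == pytest.approx(0.069375, abs=1e-8)

    @pytest.mark.parametrize("normalization", ["in_weights", "out_weights"])
    def test_fixed_point_residual_below_tolerance(self, fixture_net, normalization):
        config = RankConfig(normalization=normalization)
        res = node_rank(fixture_net, config)
        assert res.converged
        M, nodes = transition_matrix(fixture_net, normalization)
        n = len(nodes)
        R = np.array([res.values[v] for v in nodes])
        rhs = 0.85 * (M @ R) + 0.15 / n
        if normalization == "out_weights":
            dangling = M.sum(axis=0) == 0.0
            rhs += 0.85 * R[dangling].sum() / n
        assert np.abs(R - rhs).sum() < config.tolerance

    def test_values_at_least_teleport_floor(self, fixture_net):
        res = node_rank(fixture_net)
        n = len(res.values)
        for v in res.values.values():
            assert v >= 0.15 / n - 1e-15

    def test_independent_of_start_vector(self, fixture_net):
        config = RankConfig()
        res_uniform = node_rank(fixture_net, config)
        n = len(res_uniform.values)
        rng = np.random.default_rng(0)
        res_random = node_rank(fixture_net, config, start=rng.random(n))
        diff = sum(
            abs(res_uniform.values[v] - res_random.values[v])
            for v in res_uniform.values
        )
        assert diff < 10 * config.tolerance

    def test_out_weights_conserves_total_rank(self, fixture_net):
        config = RankConfig(normalization="out_weights")
        res = node_rank(fixture_net, config)
        assert sum(res.values.values()) == pytest.approx(1.0, abs=10 * config.tolerance)

    def test_out_weights_agrees_with_networkx_pagerank(self, fixture_net):
        """Independent oracle: the column-stochastic variant is standard
        weighted PageRank, so networkx must reproduce it."""
        import networkx as nx

        g = nx.DiGraph()
        for (u, v), w in fixture_net.pair_weights().items():
            g.add_edge(u, v, weight=w)
        g.add_nodes_from(fixture_net.nodes)
        reference = nx.pagerank(g, alpha=0.85, tol=1e-12, max_iter=2000, weight="weight")
        res = node_rank(fixture_net, RankConfig(normalization="out_weights"))
        for node, value in res.values.items():
            assert value == pytest.approx(reference[node], abs=1e-8)

    def test_non_convergence_flagged_not_raised(self, fixture_net):
        res = node_rank(fixture_net, RankConfig(max_iterations=2))
        assert not res.converged
        assert res.iterations == 2


class TestRanking:
    def test_star_ranks_hub_first(self):
        res = node_rank(edge_net(("A", "D"), ("B", "D"), ("C", "D")))
        ranked = rank_nodes(res)
        assert ranked[0][0] == "D"
        assert [n for n, _ in ranked[1:]] == ["A", "B", "C"]  # tie -> id order

    def test_uniform_cycle_ties_break_by_id(self):
        res = node_rank(cycle_net(4))
        assert [n for n, _ in rank_nodes(res)] == ["N00", "N01", "N02", "N03"]

    def test_top_k(self):
        res = node_rank(cycle_net(4))
        assert len(rank_nodes(res, 2)) == 2
        assert len(rank_nodes(res, 99)) == 4
        with pytest.raises(ValueError):
            rank_nodes(res, 0)
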