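"""The entropy-based centrality: ego subgraphs, entropies, two-hop influence.

Numeric expectations on the 8-airport fixture come from the published
worked example; structural conventions (induced ego edges, in∪out neighbor
membership, out-edge two-hop traversal) are cross-checked against the
brute-force oracle on random graphs, including non-reciprocal ones the
fully reciprocal fixture cannot discriminate.
"""

import math

import pytest
from hypothesis import given, settings, strategies as st

import _oracle as oracle
from entrank import (
    Coefficients,
    build_ego_subgraph,
    frequency_entropy,
    from_edge_list,
    indirect_influence,
    indirect_influence_on,
    local_influence,
    structural_entropy,
    subgraph_degree_centrality,
    total_influence,
    two_hop_neighbors,
)
from conftest import small_random_networks

TOL = 1e-4


class TestCoefficients:
    @pytest.mark.parametrize(
        "kw",
        [
            {"omega1": 0.5, "omega2": 0.6},
            {"omega1": -0.1, "omega2": 1.1},
            {"theta1": 0.9, "theta2": 0.2},
            {"log_base": 1.0},
            {"log_base": -2.0},
        ],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            Coefficients(**kw)

    def test_defaults(self):
        c = Coefficients()
        assert (c.omega1, c.omega2, c.theta1, c.theta2, c.log_base) == (
            0.4, 0.6, 0.6, 0.4, 10.0,
        )


class TestEgoSubgraph:
    def test_focal_b(self, toy):
        sub = build_ego_subgraph(toy, "B")
        assert sub.members == frozenset("BACDE")
        assert sub.g.number_of_edges() == 14  # induced, incl. neighbor-neighbor
        assert sub.n_neighbors == 4

    def test_focal_h_neighbor_edges_excluded(self, toy):
        sub = build_ego_subgraph(toy, "H")
        assert sub.members == frozenset("HCG")
        assert set(sub.g.edges) == {("C", "H"), ("H", "C"), ("G", "H"), ("H", "G")}

    def test_isolated_node(self):
        net = from_edge_list([("X", "Y", 1)], directed=True)
        net.g.add_node("Z")
        sub = build_ego_subgraph(net, "Z")
        assert sub.members == frozenset({"Z"})
        assert sub.g.number_of_edges() == 0

    def test_unknown_node(self, toy):
        with pytest.raises(KeyError):
            build_ego_subgraph(toy, "Z")


class TestSubgraphDegreeCentrality:
    @pytest.mark.parametrize(
        "v,expected", [("B", 8), ("A", 4), ("C", 4), ("D", 6), ("E", 6)]
    )
    def test_published_subgraph_b(self, toy, v, expected):
        sub = build_ego_subgraph(toy, "B")
        assert subgraph_degree_centrality(sub, v) == expected

    def test_one_way_edge(self):
        net = from_edge_list([("X", "Y", 3)], directed=True)
        sub = build_ego_subgraph(net, "X")
        assert subgraph_degree_centrality(sub, "X") == 1  # pure out-degree

    def test_undirected_counts_each_tie_once(self):
        net = from_edge_list([("X", "Y", 1), ("Y", "Z", 1)], directed=False)
        sub = build_ego_subgraph(net, "Y")
        assert subgraph_degree_centrality(sub, "Y") == 2

    def test_outside_member_raises(self, toy):
        sub = build_ego_subgraph(toy, "H")
        with pytest.raises(KeyError):
            subgraph_degree_centrality(sub, "A")


class TestEntropies:
    def test_structural_entropy_of_b(self, toy):
        assert structural_entropy(toy, "B") == pytest.approx(0.6836, abs=TOL)

    def test_frequency_entropy_of_b(self, toy):
        assert frequency_entropy(toy, "B") == pytest.approx(0.5898, abs=TOL)

    def test_uniform_sdc_maximizes_structural_entropy(self):
        # 4-clique (undirected): every member has equal SDC
        rows = [(a, b, 1) for a in "wxyz" for b in "wxyz" if a < b]
        net = from_edge_list(rows, directed=False)
        assert structural_entropy(net, "w") == pytest.approx(math.log10(4))

    def test_single_out_edge_frequency_entropy_zero(self):
        net = from_edge_list([("X", "Y", 7), ("Y", "X", 2), ("Y", "Z", 2)], True)
        assert frequency_entropy(net, "X") == 0.0

    def test_equal_weights_frequency_entropy_log_m(self):
        net = from_edge_list([("X", c, 3) for c in "abcde"], directed=True)
        assert frequency_entropy(net, "X") == pytest.approx(math.log10(5))

    def test_isolated_node_entropies_zero(self):
        net = from_edge_list([("X", "Y", 1)], directed=True)
        net.g.add_node("Z")
        assert structural_entropy(net, "Z") == 0.0
        assert frequency_entropy(net, "Z") == 0.0

    def test_log_base_conversion(self, toy):
        c2 = Coefficients(log_base=2.0)
        assert structural_entropy(toy, "B", c2) == pytest.approx(
            structural_entropy(toy, "B") * math.log2(10), rel=1e-12
        )


class TestLocalInfluence:
    @pytest.mark.parametrize(
        "v,expected", [("B", 0.6273), ("E", 0.6956), ("A", 0.4736), ("F", 0.4930)]
    )
    def test_published_values(self, toy, v, expected):
        assert local_influence(toy, v) == pytest.approx(expected, abs=TOL)


class TestTwoHop:
    def test_b_targets_and_intermediates(self, toy):
        targets = two_hop_neighbors(toy, "B")
        assert targets == {
            "F": frozenset({"A", "E"}),
            "G": frozenset({"E"}),
            "H": frozenset({"C"}),
        }

    def test_e_targets(self, toy):
        assert set(two_hop_neighbors(toy, "E")) == {"A", "H"}

    def test_dead_end_has_none(self):
        net = from_edge_list([("X", "Y", 1)], directed=True)
        assert two_hop_neighbors(net, "X") == {}

    def test_follows_edge_direction(self):
        # X->Y<-Z: Z is not two-hop-reachable from X
        net = from_edge_list([("X", "Y", 1), ("Z", "Y", 1)], directed=True)
        assert two_hop_neighbors(net, "X") == {}


class TestIndirectInfluence:
    def test_double_path_term(self, toy):
        li = {v: local_influence(toy, v) for v in toy.nodes}
        got = indirect_influence_on(toy, "B", "F", li)
        assert got == pytest.approx(
            (li["B"] * li["A"] + li["B"] * li["E"]) / 2, rel=1e-12
        )

    def test_single_path_term(self, toy):
        li = {v: local_influence(toy, v) for v in toy.nodes}
        got = indirect_influence_on(toy, "B", "H", li)
        assert got == pytest.approx(li["B"] * li["C"], rel=1e-12)

    def test_non_two_hop_target_rejected(self, toy):
        li = {v: 1.0 for v in toy.nodes}
        with pytest.raises(ValueError):
            indirect_influence_on(toy, "B", "A", li)  # A is one-hop

    def test_zero_local_influence_propagates(self, toy):
        li = {v: 0.0 for v in toy.nodes}
        assert indirect_influence(toy, "B", li) == 0.0

    def test_published_indirect_of_a(self, toy):
        li = {v: local_influence(toy, v) for v in toy.nodes}
        assert indirect_influence(toy, "A", li) == pytest.approx(0.2625, abs=TOL)

    def test_no_two_hop_gives_zero(self):
        net = from_edge_list([("X", "Y", 1)], directed=True)
        assert indirect_influence(net, "X", {"X": 1.0, "Y": 1.0}) == 0.0


class TestTotalInfluence:
    def test_published_ranking(self, toy):
        table = total_influence(toy)
        assert list(table["node"]) == list("EBDCGFAH")
        assert list(table["rank"]) == list(range(1, 9))

    def test_published_totals(self, toy):
        table = total_influence(toy).set_index("node")
        for v, expected in [("D", 0.4357), ("G", 0.4197), ("F", 0.4124),
                            ("A", 0.3892)]:
            assert table.loc[v, "total_influence"] == pytest.approx(expected, abs=TOL)

    def test_table_internal_consistency(self, toy):
        c = Coefficients()
        t = total_influence(toy, c)
        for _, row in t.iterrows():
            assert row["local_influence"] == pytest.approx(
                c.omega1 * row["structural_entropy"]
                + c.omega2 * row["frequency_entropy"], rel=1e-12,
            )
            assert row["total_influence"] == pytest.approx(
                c.theta1 * row["local_influence"]
                + c.theta2 * row["indirect_influence"], rel=1e-12,
            )

    def test_edgeless_graph_all_tied(self):
        net = from_edge_list([("A", "B", 1)], directed=True)
        net.g.remove_edge("A", "B")
        t = total_influence(net)
        assert set(t["total_influence"]) == {0.0}
        assert t["tied"].all()
        assert sorted(t["rank"]) == [1, 2]

    def test_theta2_zero_reduces_to_local_ranking(self):
        for net in small_random_networks(6):
            full = total_influence(net, Coefficients(theta1=1.0, theta2=0.0))
            by_local = full.sort_values(
                ["local_influence", "node"], ascending=[False, True],
                key=lambda c: c.map(str) if c.name == "node" else c,
            )
            assert list(by_local["node"]) == list(full["node"])


class TestOracleEquivalence:
    """Literal brute-force enumeration agrees with the implementation."""

    def test_directed_random_graphs(self):
        for net in small_random_networks(30, seed0=300):
            edges = net.edge_weights()
            nodes = net.nodes
            li = {v: local_influence(net, v) for v in nodes}
            expected_total = oracle.total_influence(edges, nodes)
            for v in nodes:
                sub = build_ego_subgraph(net, v)
                assert sub.members == frozenset(oracle.ego_members(edges, v))
                for u in sub.members:
                    assert subgraph_degree_centrality(sub, u) == oracle.sdc(
                        edges, set(sub.members), u
                    )
                assert structural_entropy(net, v) == pytest.approx(
                    oracle.structural_entropy(edges, v), abs=1e-12
                )
                assert frequency_entropy(net, v) == pytest.approx(
                    oracle.frequency_entropy(edges, v), abs=1e-12
                )
                got_2hop = {p: set(js) for p, js in two_hop_neighbors(net, v).items()}
                assert got_2hop == oracle.two_hop(edges, v)
                assert indirect_influence(net, v, li) == pytest.approx(
                    oracle.indirect_influence(edges, v, li), abs=1e-12
                )
            table = total_influence(net).set_index("node")
            for v in nodes:
                assert table.loc[v, "total_influence"] == pytest.approx(
                    expected_total[v], abs=1e-12
                )

    def test_undirected_random_graphs(self):
        for net in small_random_networks(10, directed=False, seed0=900):
            edges = net.edge_weights()  # symmetric storage
            for v in net.nodes:
                sub = build_ego_subgraph(net, v)
                for u in sub.members:
                    assert subgraph_degree_centrality(sub, u) == oracle.sdc(
                        edges, set(sub.members), u, directed=False
                    )
                assert structural_entropy(net, v) == pytest.approx(
                    oracle.structural_entropy(edges, v, directed=False), abs=1e-12
                )
                assert frequency_entropy(net, v) == pytest.approx(
                    oracle.frequency_entropy(edges, v), abs=1e-12
                )


class TestInvariances:
    def test_permutation_equivariance(self):
        for net in small_random_networks(8, seed0=500):
            mapping = {v: f"n{net.n_nodes - 1 - int(v):03d}" for v in net.nodes}
            relabeled = from_edge_list(
                [(mapping[u], mapping[v], w) for (u, v), w in net.edge_weights().items()],
                directed=True,
            )
            relabeled.g.add_nodes_from(mapping.values())
            t1 = total_influence(net).set_index("node")
            t2 = total_influence(relabeled).set_index("node")
            for v in net.nodes:
                assert t2.loc[mapping[v], "total_influence"] == pytest.approx(
                    t1.loc[v, "total_influence"], rel=1e-12, abs=1e-15
                )

    @pytest.mark.parametrize("scale", [0.5, 3.0, 1e4])
    def test_weight_rescaling_invariance(self, toy, scale):
        scaled = from_edge_list(
            [(u, v, w * scale) for (u, v), w in toy.edge_weights().items()], True
        )
        t1 = total_influence(toy).set_index("node")
        t2 = total_influence(scaled).set_index("node")
        for v in toy.nodes:
            for col in ("structural_entropy", "frequency_entropy", "total_influence"):
                assert t2.loc[v, col] == pytest.approx(t1.loc[v, col], rel=1e-9)

    def test_entropy_bounds_random_graphs(self):
        for net in small_random_networks(15, seed0=700):
            for v in net.nodes:
                sub = build_ego_subgraph(net, v)
                m = sub.n_neighbors
                assert 0.0 <= structural_entropy(net, v) <= math.log10(m + 1) + 1e-12
                m_out = max(len(list(net.g.successors(v))), 1)
                assert 0.0 <= frequency_entropy(net, v) <= math.log10(m_out) + 1e-12


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    rows=st.lists(
        st.tuples(st.integers(0, 7), st.integers(0, 7), st.integers(1, 9)).filter(
            lambda r: r[0] != r[1]
        ),
        min_size=1,
        max_size=30,
        unique_by=lambda r: (r[0], r[1]),
    )
)
def test_entropy_bounds_property(rows):
    """Both entropies stay within their uniform-distribution upper bounds."""
    net = from_edge_list(rows, directed=True)
    for v in net.nodes:
        sub = build_ego_subgraph(net, v)
        assert 0.0 <= structural_entropy(net, v) <= math.log10(
            sub.n_neighbors + 1
        ) + 1e-12
        m_out = len(list(net.g.successors(v)))
        bound = math.log10(m_out) if m_out > 1 else 0.0
        assert 0.0 <= frequency_entropy(net, v) <= bound + 1e-12
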