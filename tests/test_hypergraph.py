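"""Hypergraph model and B-visit traversal."""

import random

import pytest

from brelax import (
    DirectedHypergraph,
    b_visit,
    classify_hyperedges,
    size_of,
    validate_hypergraph,
)
from brelax.hypergraph import NodeAttributes, hyperedge_cardinality

from conftest import make_random_hypergraph, naive_b_connected, random_order_b_visit


class TestConstruction:
    def test_rejects_empty_tail_or_head(self):
        h = DirectedHypergraph()
        with pytest.raises(ValueError):
            h.add_hyperedge("bad", set(), {"x"})
        with pytest.raises(ValueError):
            h.add_hyperedge("bad", {"x"}, set())

    def test_rejects_duplicate_edge_id(self, toy1):
        with pytest.raises(ValueError, match="duplicate"):
            toy1_copy = DirectedHypergraph(
                hyperedges=dict(toy1.hyperedges)
            )
            toy1_copy.add_hyperedge("e1", {"a"}, {"b"})

    def test_duplicate_topology_under_distinct_ids_kept(self):
        h = DirectedHypergraph(
            hyperedges={"e1": ({"a"}, {"b"}), "e2": ({"a"}, {"b"})}
        )
        assert len(h.hyperedges) == 2
        assert b_visit(h, {"a"}).connected == {"a", "b"}

    def test_nodes_include_isolated_and_edge_members(self):
        h = DirectedHypergraph(nodes={"iso"}, hyperedges={"e": ({"x"}, {"y"})})
        assert h.nodes == {"iso", "x", "y"}

    def test_tail_head_overlap_permitted(self):
        # auto-catalysis: a node in both tail and head is structurally legal
        h = DirectedHypergraph(hyperedges={"e": ({"a", "b"}, {"b", "c"})})
        assert validate_hypergraph(h) == []
        assert b_visit(h, {"a", "b"}).connected == {"a", "b", "c"}


class TestValidate:
    def test_well_formed_fixture_clean(self, toy1):
        assert validate_hypergraph(toy1) == []

    def test_unknown_node_reference_reported(self, toy1):
        # bypass construction indexing to simulate a corrupted structure
        h = DirectedHypergraph(hyperedges=dict(toy1.hyperedges))
        h._nodes.discard("f")
        violations = validate_hypergraph(h)
        assert len(violations) == 1 and "'f'" in violations[0] and "e3" in violations[0]


class TestSize:
    @pytest.mark.parametrize(
        "edges,expected",
        [
            ({"e1": ({"a", "b"}, {"c"}), "e2": ({"c"}, {"d"}), "e3": ({"d", "f"}, {"e"})}, 8),
            ({}, 0),
            ({"e": ({"x"}, {"y"})}, 2),
        ],
    )
    def test_size_is_sum_of_cardinalities(self, edges, expected):
        assert size_of(DirectedHypergraph(hyperedges=edges)) == expected

    def test_single_edge_cardinality(self, toy1):
        assert hyperedge_cardinality(toy1, "e1") == 3
        assert hyperedge_cardinality(toy1, "e3") == 3


class TestBVisit:
    def test_toy1_from_ab(self, toy1):
        res = b_visit(toy1, {"a", "b"})
        assert res.connected == {"a", "b", "c", "d"}
        assert res.restrictive == {"e3"}
        assert res.traversed == {"e1", "e2"}

    def test_full_source_connects_everything(self, toy1):
        res = b_visit(toy1, toy1.nodes)
        assert res.connected == toy1.nodes
        assert res.restrictive == frozenset()

    def test_toy1_from_f_only_touches_e3(self, toy1):
        res = b_visit(toy1, {"f"})
        assert res.connected == {"f"}
        assert res.restrictive == {"e3"}
        assert res.traversed == frozenset()

    def test_unknown_source_node_rejected(self, toy1):
        with pytest.raises(KeyError, match="zzz"):
            b_visit(toy1, {"zzz"})

    def test_empty_source_rejected(self, toy1):
        with pytest.raises(ValueError):
            b_visit(toy1, set())

    def test_result_invariants_on_random_instances(self):
        for seed in range(20):
            h = make_random_hypergraph(seed)
            src = {sorted(h.nodes)[seed % len(h.nodes)]}
            res = b_visit(h, src)
            assert src <= res.connected
            assert not (res.restrictive & res.traversed)
            for eid in res.traversed:
                assert h.tail(eid) <= res.connected


class TestBVisitProperties:
    def test_matches_fixed_point_oracle_small_random(self):
        """B-visit equals the naive definition fixed point on tiny instances."""
        for seed in range(40):
            h = make_random_hypergraph(seed, n=10, m=14)
            for s in list(sorted(h.nodes))[:4]:
                assert b_visit(h, {s}).connected == naive_b_connected(h, {s})

    def test_order_independence(self):
        rng = random.Random(1234)
        for seed in range(50):
            h = make_random_hypergraph(seed, n=15, m=25)
            src = set(list(sorted(h.nodes))[: 1 + seed % 3])
            ref = b_visit(h, src)
            for _ in range(10):
                b, r, x = random_order_b_visit(h, src, rng)
                assert (b, r, x) == (ref.connected, ref.restrictive, ref.traversed)

    def test_extensivity_monotonicity_idempotence(self):
        for seed in range(15):
            h = make_random_hypergraph(seed)
            nodes = sorted(h.nodes)
            small = set(nodes[:2])
            large = small | set(nodes[2:5])
            b_small = b_visit(h, small).connected
            b_large = b_visit(h, large).connected
            assert small <= b_small  # extensivity
            assert b_small <= b_large  # monotonicity
            assert b_visit(h, b_small).connected == b_small  # idempotence

    def test_graph_specialization_equals_bfs(self):
        import networkx as nx

        for seed in range(10):
            h = make_random_hypergraph(seed, n=15, m=25, tail_size=(1, 1), head_size=(1, 1))
            g = nx.DiGraph(
                (next(iter(t)), next(iter(hd))) for t, hd in h.hyperedges.values()
            )
            g.add_nodes_from(h.nodes)
            for s in sorted(h.nodes)[:5]:
                reach = set(nx.descendants(g, s)) | {s}
                assert b_visit(h, {s}).connected == reach


class TestClassify:
    def test_toy1_from_a(self, toy1):
        assert classify_hyperedges(toy1, {"a"}) == {
            "e1": "restrictive",
            "e2": "untouched",
            "e3": "untouched",
        }

    def test_toy1_from_ab(self, toy1):
        assert classify_hyperedges(toy1, {"a", "b"}) == {
            "e1": "traversable",
            "e2": "traversable",
            "e3": "restrictive",
        }

    def test_full_source_all_traversable(self, toy1):
        assert set(classify_hyperedges(toy1, toy1.nodes).values()) == {"traversable"}

    def test_consistent_with_b_visit_sets(self):
        for seed in range(10):
            h = make_random_hypergraph(seed)
            src = set(sorted(h.nodes)[:2])
            res = b_visit(h, src)
            cls = classify_hyperedges(h, src)
            assert {e for e, c in cls.items() if c == "traversable"} == res.traversed
            assert {e for e, c in cls.items() if c == "restrictive"} == res.restrictive


class TestNodeAttributes:
    def test_type_filter_and_check(self, toy1):
        attrs = NodeAttributes()
        attrs.set("a", "protein", "Protein A")
        attrs.set("b", "smallmolecule")
        assert attrs.of_type("smallmolecule") == {"b"}
        assert attrs.check_against(toy1) == []
        attrs.set("nope", "protein")
        assert len(attrs.check_against(toy1)) == 1

    def test_unknown_entity_type_rejected(self):
        with pytest.raises(ValueError):
            NodeAttributes().set("a", "metabolite")
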