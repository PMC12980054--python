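"""Temporal graph construction, consistency checking, and closure,
cross-checked against brute-force endpoint enumeration."""

import random
from itertools import combinations, product

import pytest

from clintime.closure import (
    InconsistentGraphError,
    TemporalGraph,
    build_graph,
    check_consistency,
    compute_closure,
    connected_components,
)
from clintime.schema import (
    DocumentAnnotation,
    EntityAnnotation,
    RelationAnnotation,
    Span,
    normalize_relations,
)

from endpoint_oracle import RELATION_TYPES, oracle_closure


def graph(n, edges):
    names = [f"v{i}" for i in range(n)]
    return TemporalGraph(
        vertices=names, edges={(names[a], names[b], t) for a, b, t in edges}
    )


def as_indices(edges):
    return {(int(a[1:]), int(b[1:]), t) for a, b, t in edges}


class TestBuildGraph:
    def make_doc(self, n_entities, relations):
        text = "x" * (6 * n_entities)
        ents = [
            EntityAnnotation(f"e{i}", "Date", Span(5 * i, 5 * i + 4), text[5 * i : 5 * i + 4])
            for i in range(n_entities)
        ]
        rels = [
            RelationAnnotation(f"R{i}", t, a, b) for i, (a, b, t) in enumerate(relations)
        ]
        return DocumentAnnotation("d", "a", text, entities=ents, relations=rels)

    def test_vertices_and_edges_conserved(self):
        doc = self.make_doc(3, [("e0", "e1", "BEFORE"), ("e1", "e2", "CONTAINS")])
        g = build_graph(normalize_relations(doc))
        assert len(g.vertices) == 3 and len(g.edges) == 2 and not g.closed

    def test_isolated_vertices(self):
        g = build_graph(self.make_doc(4, []))
        assert len(connected_components(g)) == 4


class TestConnectivity:
    def test_chain_is_one_component(self):
        g = graph(3, [(0, 1, "BEFORE"), (1, 2, "BEFORE")])
        assert len(connected_components(g)) == 1

    def test_two_disjoint_pairs(self):
        g = graph(4, [(0, 1, "BEFORE"), (2, 3, "OVERLAP")])
        assert len(connected_components(g)) == 2


class TestClosureExamples:
    def test_before_is_transitive(self):
        c = compute_closure(graph(3, [(0, 1, "BEFORE"), (1, 2, "BEFORE")]))
        assert ("v0", "v2", "BEFORE") in c.edges

    def test_contains_is_transitive(self):
        c = compute_closure(graph(3, [(0, 1, "CONTAINS"), (1, 2, "CONTAINS")]))
        assert ("v0", "v2", "CONTAINS") in c.edges

    def test_contains_fork_entails_nothing_between_children(self):
        c = compute_closure(graph(3, [(0, 1, "CONTAINS"), (0, 2, "CONTAINS")]))
        assert not any({a, b} == {"v1", "v2"} for a, b, _ in c.edges)

    def test_before_then_contains(self):
        c = compute_closure(graph(3, [(0, 1, "BEFORE"), (1, 2, "CONTAINS")]))
        assert ("v0", "v2", "BEFORE") in c.edges

    def test_contains_entails_overlap(self):
        c = compute_closure(graph(2, [(0, 1, "CONTAINS")]))
        assert ("v0", "v1", "OVERLAP") in c.edges

    def test_equal_start_plus_containment(self):
        c = compute_closure(graph(3, [(0, 1, "BEGINS-ON"), (0, 2, "CONTAINS")]))
        # start(v1) = start(v0) < start(v2): v1 cannot start after v2.
        assert ("v2", "v1", "CONTAINS") not in c.edges


class TestConsistency:
    def test_mutual_before_inconsistent(self):
        ok, witness = check_consistency(graph(2, [(0, 1, "BEFORE"), (1, 0, "BEFORE")]))
        assert not ok and len(witness) == 2

    def test_contains_and_before_same_pair_inconsistent(self):
        ok, _ = check_consistency(graph(2, [(0, 1, "CONTAINS"), (0, 1, "BEFORE")]))
        assert not ok

    def test_single_edge_consistent(self):
        for t in RELATION_TYPES:
            ok, w = check_consistency(graph(2, [(0, 1, t)]))
            assert ok and w == []

    def test_witness_is_minimal_subset(self):
        g = graph(4, [(0, 1, "BEFORE"), (1, 2, "BEFORE"), (2, 0, "BEFORE"), (0, 3, "OVERLAP")])
        ok, witness = check_consistency(g)
        assert not ok
        assert set(witness) <= g.edges and len(witness) == 3
        sub = TemporalGraph(vertices=list(g.vertices), edges=set(witness))
        assert not check_consistency(sub)[0]

    def test_closure_raises_with_witness(self):
        with pytest.raises(InconsistentGraphError) as exc:
            compute_closure(graph(2, [(0, 1, "BEFORE"), (1, 0, "BEFORE")]))
        assert len(exc.value.witness) == 2


def random_consistent_graph(rng, n=5, n_edges=5):
    """Sample intervals on a grid, assert true relations only."""
    while True:
        iv = []
        for _ in range(n):
            s = rng.randint(0, 8)
            e = rng.randint(s + 1, 10)
            iv.append((s, e))
        edges = set()
        for _ in range(n_edges):
            i, j = rng.sample(range(n), 2)
            (s1, e1), (s2, e2) = iv[i], iv[j]
            if e1 < s2:
                edges.add((i, j, "BEFORE"))
            elif s1 < s2 and e2 < e1:
                edges.add((i, j, "CONTAINS"))
            elif s1 == s2 and e1 != e2:
                edges.add((i, j, "BEGINS-ON"))
            elif e1 == e2 and s1 != s2:
                edges.add((i, j, "ENDS-ON"))
            elif s1 < e2 and s2 < e1 and (s1, e1) != (s2, e2):
                edges.add((i, j, "OVERLAP"))
        if edges:
            return graph(n, edges)


class TestClosureProperties:
    def test_idempotent_and_extensive(self):
        rng = random.Random(3)
        for _ in range(30):
            g = random_consistent_graph(rng)
            c1 = compute_closure(g)
            c2 = compute_closure(c1)
            assert g.edges <= c1.edges
            assert c1.edges == c2.edges

    def test_monotone(self):
        rng = random.Random(4)
        for _ in range(20):
            g = random_consistent_graph(rng, n=4, n_edges=5)
            sub_edges = set(list(sorted(g.edges))[: max(1, len(g.edges) // 2)])
            sub = TemporalGraph(vertices=list(g.vertices), edges=sub_edges)
            assert compute_closure(sub).edges <= compute_closure(g).edges

    def test_contains_always_entails_overlap(self):
        rng = random.Random(5)
        for _ in range(30):
            c = compute_closure(random_consistent_graph(rng))
            for a, b, t in c.edges:
                if t == "CONTAINS":
                    assert (a, b, "OVERLAP") in c.edges


class TestOracleEquivalence:
    """Exact agreement with exhaustive endpoint-grid enumeration."""

    def check(self, n, edges):
        expected = oracle_closure(n, edges)
        g = graph(n, edges)
        ok, _ = check_consistency(g, minimize_witness=False)
        if expected is None:
            assert not ok, edges
        else:
            assert ok, edges
            assert as_indices(compute_closure(g).edges) == expected, edges

    def test_all_single_edges_three_intervals(self):
        for i, j in ((0, 1), (1, 0)):
            for t in RELATION_TYPES:
                self.check(3, [(i, j, t)])

    def test_all_two_edge_graphs_three_intervals(self):
        pairs = [(i, j) for i, j in product(range(3), repeat=2) if i != j]
        all_edges = [(i, j, t) for i, j in pairs for t in RELATION_TYPES]
        for e1, e2 in combinations(all_edges, 2):
            self.check(3, [e1, e2])

    def test_random_three_edge_graphs_four_intervals(self):
        rng = random.Random(9)
        pairs = [(i, j) for i, j in product(range(4), repeat=2) if i != j]
        for _ in range(60):
            edges = [
                (*rng.choice(pairs), rng.choice(RELATION_TYPES)) for _ in range(3)
            ]
            self.check(4, edges)
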