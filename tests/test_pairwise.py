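"""Pairwise integration: DP entries, reconstruction, heuristic, invariants."""

import numpy as np
import pytest

from ontofuse import (ClosenessMatrix, HeuristicConfig, OntologyError,
                      build_cohesion_matrix, build_integrated_ontology,
                      build_tree, cohesion_of, exhaustive_pair_optimum,
                      heuristic_integrate, integrate_pair,
                      mapping_pair_optimum, validate_lca_preservation)
from conftest import random_pair


def members_set(onto):
    return {frozenset(nd.members) for nd in onto.nodes if nd.members}


class TestCohesionMatrix:
    def test_e1_optimal_entries(self, e1):
        cm = build_cohesion_matrix(*e1, matcher="optimal")
        assert cm.entry("a1", "b2") == 4.0
        # merge roots (1 + matching 2+3=5) beats descending (4)
        assert cm.entry("a0", "b0") == 6.0
        assert cm.value == 6.0

    def test_e1_greedy_entries(self, e1):
        cm = build_cohesion_matrix(*e1, matcher="greedy")
        # greedy child matching takes (a1,b2)=4 and blocks both 2 and 3
        assert cm.entry("a0", "b0") == 5.0
        assert cm.value == 5.0

    def test_single_vertex_base_case(self):
        t_a = build_tree([], "A", root="a0")
        t_b = build_tree([], "B", root="b0")
        m = ClosenessMatrix("A", "B", {("a0", "b0"): 2.5})
        assert build_cohesion_matrix(t_a, t_b, m, "optimal").value == 2.5

    def test_entries_dominate_closeness_and_children(self, e1):
        t_a, t_b, m = e1
        cm = build_cohesion_matrix(t_a, t_b, m, "optimal")
        dense = m.dense(t_a, t_b)
        g = cm.table
        assert np.all(g >= dense)
        for i in range(t_a.n + 1):
            for j in range(t_b.n + 1):
                for c in t_a.children[i]:
                    assert g[i, j] >= g[c, j]
                for c in t_b.children[j]:
                    assert g[i, j] >= g[i, c]
        assert g[0, 0] == g.max()

    def test_unknown_matcher(self, e1):
        with pytest.raises(OntologyError, match="matcher"):
            build_cohesion_matrix(*e1, matcher="magic")

    def test_monotone_in_closeness(self):
        rng = np.random.default_rng(5)
        for seed in range(20):
            t_a, t_b, m = random_pair(seed + 1, max_n=5)
            base = build_cohesion_matrix(t_a, t_b, m, "optimal").value
            entries = dict(
                ((a, b), s) for a, b, s in m.items())
            a = t_a.ids[int(rng.integers(1, t_a.n + 1))]
            b = t_b.ids[int(rng.integers(1, t_b.n + 1))]
            entries[(a, b)] = entries.get((a, b), 0.0) + 1.0
            bumped = build_cohesion_matrix(
                t_a, t_b, ClosenessMatrix("A", "B", entries),
                "optimal").value
            assert bumped >= base - 1e-12


class TestReconstruction:
    def test_e1_optimal_nodes(self, e1):
        onto = integrate_pair(*e1, matcher="optimal")
        assert onto.total_cohesion == 6.0
        assert members_set(onto) == {
            frozenset({("A", "a0"), ("B", "b0")}),
            frozenset({("A", "a1"), ("B", "b1")}),
            frozenset({("A", "a2"), ("B", "b2")})}

    def test_e1_greedy_nodes(self, e1):
        onto = integrate_pair(*e1, matcher="greedy")
        assert onto.total_cohesion == 5.0
        assert frozenset({("A", "a0"), ("B", "b0")}) in members_set(onto)
        assert frozenset({("A", "a1"), ("B", "b2")}) in members_set(onto)
        singles = {m for m in members_set(onto) if len(m) == 1}
        assert singles == {frozenset({("A", "a2")}), frozenset({("B", "b1")})}

    def test_all_zero_closeness_keeps_trees_apart(self, e1):
        t_a, t_b, _ = e1
        m = ClosenessMatrix("A", "B", {})
        onto = integrate_pair(t_a, t_b, m, matcher="optimal")
        assert onto.total_cohesion == 0.0
        assert all(len(nd.members) <= 1 for nd in onto.nodes)
        assert validate_lca_preservation(onto, [t_a, t_b]).ok

    def test_matcher_mismatch_detected(self, e1):
        cm = build_cohesion_matrix(*e1, matcher="greedy")
        with pytest.raises(OntologyError, match="replay"):
            build_integrated_ontology(cm, matcher="optimal")

    @pytest.mark.parametrize("matcher", ["greedy", "optimal"])
    def test_reconstruction_replays_cohesion_exactly(self, matcher):
        for seed in range(40):
            t_a, t_b, m = random_pair(seed + 100)
            cm = build_cohesion_matrix(t_a, t_b, m, matcher)
            onto = build_integrated_ontology(cm)
            assert onto.total_cohesion == cm.value
            assert cohesion_of(onto, [m]) == pytest.approx(cm.value,
                                                           abs=1e-9)
            assert validate_lca_preservation(onto, [t_a, t_b]).ok

    def test_every_source_vertex_placed_exactly_once(self):
        t_a, t_b, m = random_pair(77)
        onto = integrate_pair(t_a, t_b, m)
        placed = sorted(onto.node_of)
        expected = sorted([("A", t) for t in t_a.terms()] +
                          [("B", t) for t in t_b.terms()])
        assert placed == expected


class TestOracleEquivalence:
    def test_dp_optimal_equals_both_oracles_on_small_instances(self):
        for seed in range(60):
            t_a, t_b, m = random_pair(seed + 1)
            dp = build_cohesion_matrix(t_a, t_b, m, "optimal").value
            assert dp == exhaustive_pair_optimum(t_a, t_b, m)
            assert dp == pytest.approx(mapping_pair_optimum(t_a, t_b, m),
                                       abs=1e-12)

    def test_greedy_dp_keeps_half_of_optimal(self):
        for seed in range(60):
            t_a, t_b, m = random_pair(seed + 1)
            opt = build_cohesion_matrix(t_a, t_b, m, "optimal").value
            greedy = build_cohesion_matrix(t_a, t_b, m, "greedy").value
            assert greedy >= 0.5 * opt - 1e-12
            assert greedy <= opt + 1e-12


class TestHeuristic:
    def test_e1_beta1_trace(self, e1):
        onto = heuristic_integrate(*e1, cfg=HeuristicConfig(1.0))
        assert onto.total_cohesion == 5.0
        assert frozenset({("A", "a0"), ("B", "b0")}) in members_set(onto)
        assert frozenset({("A", "a1"), ("B", "b2")}) in members_set(onto)
        assert frozenset({("A", "a2")}) in members_set(onto)

    def test_large_beta_prefers_shallow_candidates(self):
        t_a = build_tree([], "A", root="a0")
        t_b = build_tree([("b1", "b0")], "B")
        m = ClosenessMatrix("A", "B", {("a0", "b0"): 1.0, ("a0", "b1"): 5.0})
        deep = heuristic_integrate(t_a, t_b, m, cfg=HeuristicConfig(1.0))
        assert deep.total_cohesion == 5.0  # picks the closer, deeper b1
        shallow = heuristic_integrate(t_a, t_b, m, cfg=HeuristicConfig(1e9))
        assert shallow.total_cohesion == 1.0  # rdepth penalty forces b0

    def test_zero_closeness_means_no_merges(self, e1):
        t_a, t_b, _ = e1
        onto = heuristic_integrate(t_a, t_b, ClosenessMatrix("A", "B", {}))
        assert onto.total_cohesion == 0.0
        assert all(len(nd.members) <= 1 for nd in onto.nodes)

    def test_invalid_beta(self):
        with pytest.raises(OntologyError, match="beta"):
            HeuristicConfig(0.5)

    def test_heuristic_never_beats_optimum_and_preserves_lca(self):
        for seed in range(40):
            t_a, t_b, m = random_pair(seed + 1)
            for beta in (1.0, 6.0, 100.0):
                onto = heuristic_integrate(t_a, t_b, m, HeuristicConfig(beta))
                opt = exhaustive_pair_optimum(t_a, t_b, m)
                assert onto.total_cohesion <= opt + 1e-9
                assert cohesion_of(onto, [m]) == pytest.approx(
                    onto.total_cohesion, abs=1e-12)
                assert validate_lca_preservation(onto, [t_a, t_b]).ok


def test_cohesion_of_three_way_node():
    from ontofuse import IntegratedOntology, MergedNode, MatrixBank
    nodes = [MergedNode((), None, 0.0),
             MergedNode((("O1", "x"), ("O2", "y"), ("O3", "z")), 0, 1.6)]
    onto = IntegratedOntology(nodes, 1.6, ["O1", "O2", "O3"])
    bank = MatrixBank([
        ClosenessMatrix("O1", "O2", {("x", "y"): 0.9}),
        ClosenessMatrix("O1", "O3", {("x", "z"): 0.2}),
        ClosenessMatrix("O2", "O3", {("y", "z"): 0.5})])
    assert cohesion_of(onto, bank) == pytest.approx(1.6)
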