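"""Multi-ontology integration: closeness merging, strategies, bounds."""

import pytest

from ontofuse import (ClosenessMatrix, IntegratedOntology, MatrixBank,
                      MergedNode, OntologyError, adjusted_cohesion,
                      basic_multi_integrate, build_cohesion_matrix,
                      build_tree, cohesion_of, exhaustive_multi_optimum,
                      fast_multi_integrate, greedy_multi_integrate,
                      integrate_pair, max_spanning_tree_weight,
                      merge_closeness, pairwise_score_graph,
                      validate_lca_preservation)
from ontofuse.multi import ContractionGraph
from ontofuse.synthetic import make_instance

STRATEGIES = [basic_multi_integrate, greedy_multi_integrate,
              fast_multi_integrate]


class TestMergeCloseness:
    def test_merged_node_sums_member_closeness(self):
        # node {a, b} against target term c: 0.3 + 0.2
        t1 = build_tree([], "T1", root="a")
        t2 = build_tree([], "T2", root="b")
        t3 = build_tree([], "T3", root="c")
        bank = MatrixBank([
            ClosenessMatrix("T1", "T2", {("a", "b"): 1.0}),
            ClosenessMatrix("T1", "T3", {("a", "c"): 0.3}),
            ClosenessMatrix("T2", "T3", {("b", "c"): 0.2})])
        u = fast_multi_integrate([t1, t2], bank)
        merged = merge_closeness(u, bank, t3)
        node_id = next(
            f"N{i}" for i, nd in enumerate(u.nodes) if len(nd.members) == 2)
        assert merged.get(node_id, "c") == pytest.approx(0.5)

    def test_singleton_node_passes_score_through(self):
        t1 = build_tree([], "T1", root="a")
        t2 = build_tree([], "T2", root="b")
        t3 = build_tree([], "T3", root="c")
        bank = MatrixBank([
            ClosenessMatrix("T1", "T2", {}),  # nothing merges
            ClosenessMatrix("T1", "T3", {("a", "c"): 0.3}),
            ClosenessMatrix("T2", "T3", {})])
        u = fast_multi_integrate([t1, t2], bank)
        merged = merge_closeness(u, bank, t3)
        node_id = next(f"N{i}" for i, nd in enumerate(u.nodes)
                       if nd.members == (("T1", "a"),))
        assert merged.get(node_id, "c") == pytest.approx(0.3)

    def test_e2_merged_pair_vs_third(self, e2):
        (t1, t2, t3), bank = e2
        u = fast_multi_integrate([t1, t2], bank)
        merged = merge_closeness(u, bank, t3)
        node_id = next(
            f"N{i}" for i, nd in enumerate(u.nodes) if len(nd.members) == 2)
        assert merged.get(node_id, "z") == pytest.approx(0.7)

    def test_missing_matrix_raises(self):
        t1 = build_tree([], "T1", root="a")
        t2 = build_tree([], "T2", root="b")
        t3 = build_tree([], "T3", root="c")
        bank = MatrixBank([ClosenessMatrix("T1", "T2", {("a", "b"): 1.0})])
        u = fast_multi_integrate([t1, t2], bank)
        with pytest.raises(OntologyError, match="missing closeness"):
            merge_closeness(u, bank, t3)


class TestAdjustedCohesion:
    def test_two_originals_equals_pairwise_score(self, e1):
        t_a, t_b, m = e1
        ua = IntegratedOntology.from_tree(t_a)
        ub = IntegratedOntology.from_tree(t_b)
        g = build_cohesion_matrix(t_a, t_b, m, "optimal").value
        assert adjusted_cohesion(ua, ub, [m], "optimal") == pytest.approx(g)

    def test_division_by_member_counts(self, e2):
        (t1, t2, t3), bank = e2
        u12 = fast_multi_integrate([t1, t2], bank, "optimal")
        u3 = IntegratedOntology.from_tree(t3)
        # weight increase of integrating {T1,T2} with T3 is 0.2 + 0.5
        assert adjusted_cohesion(u12, u3, bank, "optimal") == pytest.approx(
            0.7 / 2)

    def test_zero_cross_closeness(self):
        t1 = build_tree([], "T1", root="a")
        t2 = build_tree([], "T2", root="b")
        assert adjusted_cohesion(IntegratedOntology.from_tree(t1),
                                 IntegratedOntology.from_tree(t2),
                                 [ClosenessMatrix("T1", "T2", {})]) == 0.0

    def test_overlapping_member_sets_rejected(self, e1):
        t_a, _, m = e1
        u = IntegratedOntology.from_tree(t_a)
        with pytest.raises(OntologyError, match="share"):
            adjusted_cohesion(u, u, [m])


class TestStrategies:
    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_e2_full_merge(self, e2, strategy):
        trees, bank = e2
        onto = strategy(list(trees), bank, "optimal")
        assert onto.total_cohesion == pytest.approx(1.6)
        assert any(len(nd.members) == 3 for nd in onto.nodes)
        assert cohesion_of(onto, bank) == pytest.approx(1.6)
        assert validate_lca_preservation(onto, trees).ok

    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_k2_reduces_to_pairwise(self, e1, strategy):
        t_a, t_b, m = e1
        direct = integrate_pair(t_a, t_b, m, "optimal")
        multi = strategy([t_a, t_b], [m], "optimal")
        assert multi.total_cohesion == pytest.approx(direct.total_cohesion)

    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_k1_rejected(self, e1, strategy):
        t_a, _, m = e1
        with pytest.raises(OntologyError, match="at least two"):
            strategy([t_a], [m])

    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_all_zero_matrices_single_tree_no_merges(self, strategy):
        trees = [build_tree([(f"c{i}", f"r{i}")], f"T{i}") for i in range(3)]
        bank = MatrixBank([
            ClosenessMatrix(f"T{i}", f"T{j}", {})
            for i in range(3) for j in range(i + 1, 3)])
        onto = strategy(trees, bank)
        assert onto.total_cohesion == 0.0
        assert all(len(nd.members) <= 1 for nd in onto.nodes)
        assert len(onto.node_of) == 6  # every vertex placed once
        assert validate_lca_preservation(onto, trees).ok

    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_random_instances_consistent_and_lca_preserving(self, strategy):
        for rep in range(5):
            inst = make_instance(4, 8, seed=21, replicate=rep)
            onto = strategy(inst.trees, inst.matrices)
            assert cohesion_of(onto, inst.matrices) == pytest.approx(
                onto.total_cohesion, abs=1e-9)
            assert validate_lca_preservation(onto, inst.trees).ok


class TestContractionGraph:
    def test_max_edge_selection_and_tie_break(self):
        weights = {frozenset({("A",), ("B",)}): 5.0,
                   frozenset({("A",), ("C",)}): 1.0,
                   frozenset({("B",), ("C",)}): 1.0}
        g = ContractionGraph(units={}, weights=weights)
        assert g.max_edge() == (("A",), ("B",))
        tied = ContractionGraph(units={}, weights={
            frozenset({("B",), ("C",)}): 2.0,
            frozenset({("A",), ("C",)}): 2.0})
        assert tied.max_edge() == (("A",), ("C",))

    def test_e2_initial_graph_and_mst(self, e2):
        trees, bank = e2
        g = pairwise_score_graph(list(trees), bank, "optimal")
        assert sorted(g.weights.values()) == pytest.approx([0.2, 0.5, 0.9])
        assert max_spanning_tree_weight(g) == pytest.approx(1.4)

    def test_e2_fast_contracts_heaviest_first(self, e2):
        trees, bank = e2
        g = pairwise_score_graph(list(trees), bank, "optimal")
        assert g.max_edge() == (("T1",), ("T2",))


class TestBounds:
    def test_fast_dominates_initial_mst(self):
        for rep in range(3):
            inst = make_instance(5, 12, seed=31, replicate=rep)
            g = pairwise_score_graph(inst.trees, inst.matrices)
            mst = max_spanning_tree_weight(g)
            onto = fast_multi_integrate(inst.trees, inst.matrices, graph=g)
            assert onto.total_cohesion >= mst - 1e-9

    def test_fast_within_1_over_k_minus_1_of_optimum(self):
        for rep in range(10):
            inst = make_instance(3, 4, seed=41, replicate=rep)
            opt = exhaustive_multi_optimum(inst.trees, inst.matrices)
            fast = fast_multi_integrate(inst.trees, inst.matrices, "optimal")
            assert fast.total_cohesion >= 0.5 * opt - 1e-9
            assert fast.total_cohesion <= opt + 1e-9

    def test_multi_optimum_bounded_by_pairwise_sum(self):
        for rep in range(10):
            inst = make_instance(3, 4, seed=41, replicate=rep)
            opt = exhaustive_multi_optimum(inst.trees, inst.matrices)
            pair_sum = sum(pairwise_score_graph(
                inst.trees, inst.matrices, "optimal").weights.values())
            assert opt <= pair_sum + 1e-9
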