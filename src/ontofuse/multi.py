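"""Integration of k > 2 ontologies by repeated pairwise integration.

A merged unit (an :class:`~ontofuse.pairwise.IntegratedOntology`) can itself
be integrated with another unit: its node tree plays the role of an ontology
tree, and the closeness between a merged node Z and a node C of the other
side is the sum of the base closeness scores over all cross-ontology member
pairs, generalising M_{T12,T3}(X, c) = M_{T1,T3}(a, c) + M_{T2,T3}(b, c).

Three strategies are provided:

``basic``
    Fold the ontologies in input order.  Fastest, ignores all cohesion
    information.
``greedy``
    Maintain an inter-ontology score table of *adjusted cohesion* (the
    cross-pair weight increase of integrating two units divided by
    |X| * |Y|, correcting the bias toward already-large units) and always
    integrate the best-scoring active pair, rescoring the new unit against
    the survivors.
``fast``
    Compute the pairwise maximum-cohesion graph once, then perform k - 1
    max-edge contractions, merging parallel edges by taking the maximum of
    the two stale weights.  Updated edge weights can only grow, so the
    result is lower-bounded by the maximum spanning tree of the initial
    graph and, with optimal pairwise matching, by 1/(k-1) of the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import ClosenessMatrix, MatrixBank, OntologyError, OntologyTree
from .pairwise import (IntegratedOntology, MergedNode, build_cohesion_matrix,
                       build_integrated_ontology)

__all__ = [
    "ContractionGraph", "adjusted_cohesion", "basic_multi_integrate",
    "fast_multi_integrate", "greedy_multi_integrate", "merge_closeness",
    "pairwise_score_graph",
]


def _unit_key(unit: IntegratedOntology) -> tuple[str, ...]:
    return unit.ontology_ids


def _view_tree(unit: IntegratedOntology) -> OntologyTree:
    """The unit's node tree as an OntologyTree over synthetic node ids.

    Node ids are zero-padded indices so that lexicographic order equals
    node order and re-indexing inside OntologyTree is the identity.
    """
    width = len(str(len(unit.nodes)))
    ids: list[str | None] = [None]
    parent = [-1]
    for i, nd in enumerate(unit.nodes):
        ids.append(f"N{i:0{width}d}")
        parent.append(0 if i == 0 else nd.parent + 1)  # type: ignore[operator]
    return OntologyTree("+".join(unit.ontology_ids), ids, parent)


def _cross_closeness_units(u: IntegratedOntology, v: IntegratedOntology,
                           bank: MatrixBank) -> np.ndarray:
    """Dense cross-closeness between the nodes of two units."""
    out = np.zeros((len(u.nodes), len(v.nodes)))
    row_of: dict[tuple[str, str], int] = {}
    for i, nd in enumerate(u.nodes):
        for member in nd.members:
            row_of[member] = i
    col_of: dict[tuple[str, str], int] = {}
    for j, nd in enumerate(v.nodes):
        for member in nd.members:
            col_of[member] = j
    for ont_u in u.ontology_ids:
        for ont_v in v.ontology_ids:
            if not bank.has(ont_u, ont_v):
                raise OntologyError(
                    f"missing closeness matrix for pair ({ont_u!r}, {ont_v!r})")
            for a, b, s in bank.matrix(ont_u, ont_v).items():
                i = row_of.get((ont_u, a))
                j = col_of.get((ont_v, b))
                if i is not None and j is not None:
                    out[i, j] += s
    return out


def merge_closeness(onto_xy: IntegratedOntology,
                    matrices: MatrixBank | Iterable[ClosenessMatrix],
                    target: OntologyTree) -> ClosenessMatrix:
    """Closeness between the nodes of a merged unit and a target ontology.

    Entry (Z, c) sums, over the members v of node Z, the base closeness
    between v and term c.  Rows are keyed by the unit's node ids (as used by
    its tree view), columns by the target's term ids.
    """
    bank = matrices if isinstance(matrices, MatrixBank) else MatrixBank(matrices)
    tgt = IntegratedOntology.from_tree(target)
    arr = _cross_closeness_units(onto_xy, tgt, bank)
    view = _view_tree(onto_xy)
    # Column 0 of the lifted target is its memberless root: drop it and key
    # the remaining columns by real term ids.
    return ClosenessMatrix.from_array(
        view.ontology_id, target.ontology_id,
        [view.ids[i + 1] for i in range(len(onto_xy.nodes))],
        list(target.terms()), arr[:, 1:])


def _integrate_units(u: IntegratedOntology, v: IntegratedOntology,
                     bank: MatrixBank, matcher: str
                     ) -> tuple[IntegratedOntology, float]:
    """Pairwise-integrate two units; returns (merged unit, weight increase)."""
    ta, tb = _view_tree(u), _view_tree(v)
    cross = _cross_closeness_units(u, v, bank)
    m = ClosenessMatrix.from_array(ta.ontology_id, tb.ontology_id,
                                   ta.terms(), tb.terms(), cross)
    cm = build_cohesion_matrix(ta, tb, m, matcher)
    merged_view = build_integrated_ontology(cm)
    # Flatten: each view node refers to nodes of u and v; take the union of
    # their members, sum their weights, and add the cross weight.
    nodes: list[MergedNode] = []
    for i, nd in enumerate(merged_view.nodes):
        members: tuple[tuple[str, str], ...] = ()
        weight = float(nd.weight)
        for ont, term in nd.members:
            src = u if ont == ta.ontology_id else v
            inner = src.nodes[int(term[1:])]
            members += inner.members
            weight += inner.weight
        nodes.append(MergedNode(members, nd.parent, weight))
    total = u.total_cohesion + v.total_cohesion + cm.value
    merged = IntegratedOntology(nodes, total,
                                u.ontology_ids + v.ontology_ids)
    return merged, cm.value


def adjusted_cohesion(t_x: IntegratedOntology, t_y: IntegratedOntology,
                      matrices: MatrixBank | Iterable[ClosenessMatrix],
                      matcher: str = "greedy") -> float:
    """Cross-pair weight increase of integrating two units, / (|X| * |Y|).

    |X| and |Y| count member ontologies, so for two original (single)
    ontologies this equals the plain maximum cohesion score.
    """
    bank = matrices if isinstance(matrices, MatrixBank) else MatrixBank(matrices)
    if set(t_x.ontology_ids) & set(t_y.ontology_ids):
        raise OntologyError("units share member ontologies")
    ta, tb = _view_tree(t_x), _view_tree(t_y)
    cross = _cross_closeness_units(t_x, t_y, bank)
    m = ClosenessMatrix.from_array(ta.ontology_id, tb.ontology_id,
                                   ta.terms(), tb.terms(), cross)
    cm = build_cohesion_matrix(ta, tb, m, matcher)
    return cm.value / (len(t_x.ontology_ids) * len(t_y.ontology_ids))


@dataclass
class ContractionGraph:
    """Complete weighted graph over active (possibly merged) ontologies."""

    units: dict[tuple[str, ...], IntegratedOntology]
    weights: dict[frozenset[tuple[str, ...]], float] = field(default_factory=dict)

    def max_edge(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """Heaviest edge; ties broken by the smallest ontology-id pair."""
        best = None
        best_rank = None
        for pair, w in self.weights.items():
            k1, k2 = sorted(pair)
            rank = (-w, k1, k2)
            if best_rank is None or rank < best_rank:
                best_rank = rank
                best = (k1, k2)
        if best is None:
            raise OntologyError("contraction graph has no edges")
        return best


def _lift_all(trees: Sequence[OntologyTree]) -> dict[tuple[str, ...],
                                                     IntegratedOntology]:
    if len(trees) < 2:
        raise OntologyError("need at least two ontologies to integrate")
    if len({t.ontology_id for t in trees}) != len(trees):
        raise OntologyError("duplicate ontology ids")
    return {(t.ontology_id,): IntegratedOntology.from_tree(t) for t in trees}


def _as_bank(matrices) -> MatrixBank:
    return matrices if isinstance(matrices, MatrixBank) else MatrixBank(matrices)


def basic_multi_integrate(trees: Sequence[OntologyTree],
                          matrices: MatrixBank | Iterable[ClosenessMatrix],
                          matcher: str = "greedy") -> IntegratedOntology:
    """Fold the ontologies in input order, ignoring cohesion information."""
    bank = _as_bank(matrices)
    _lift_all(trees)  # validation
    acc = IntegratedOntology.from_tree(trees[0])
    for tree in trees[1:]:
        acc, _ = _integrate_units(acc, IntegratedOntology.from_tree(tree),
                                  bank, matcher)
    return acc


def greedy_multi_integrate(trees: Sequence[OntologyTree],
                           matrices: MatrixBank | Iterable[ClosenessMatrix],
                           matcher: str = "greedy") -> IntegratedOntology:
    """Always integrate the active pair with the best adjusted cohesion."""
    bank = _as_bank(matrices)
    units = _lift_all(trees)
    weights: dict[frozenset, float] = {}
    keys = sorted(units)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            weights[frozenset((keys[i], keys[j]))] = adjusted_cohesion(
                units[keys[i]], units[keys[j]], bank, matcher)
    graph = ContractionGraph(units, weights)
    while len(graph.units) > 1:
        k1, k2 = graph.max_edge()
        merged, _ = _integrate_units(graph.units.pop(k1),
                                     graph.units.pop(k2), bank, matcher)
        graph.weights = {p: w for p, w in graph.weights.items()
                         if k1 not in p and k2 not in p}
        mk = _unit_key(merged)
        for other_key, other in graph.units.items():
            graph.weights[frozenset((mk, other_key))] = adjusted_cohesion(
                merged, other, bank, matcher)
        graph.units[mk] = merged
    return next(iter(graph.units.values()))


def pairwise_score_graph(trees: Sequence[OntologyTree],
                         matrices: MatrixBank | Iterable[ClosenessMatrix],
                         matcher: str = "greedy") -> ContractionGraph:
    """Initial contraction graph: pairwise maximum cohesion scores."""
    bank = _as_bank(matrices)
    units = _lift_all(trees)
    weights: dict[frozenset, float] = {}
    keys = sorted(units)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            u, v = units[keys[i]], units[keys[j]]
            ta, tb = _view_tree(u), _view_tree(v)
            cross = _cross_closeness_units(u, v, bank)
            m = ClosenessMatrix.from_array(ta.ontology_id, tb.ontology_id,
                                           ta.terms(), tb.terms(), cross)
            weights[frozenset((keys[i], keys[j]))] = build_cohesion_matrix(
                ta, tb, m, matcher).value
    return ContractionGraph(units, weights)


def fast_multi_integrate(trees: Sequence[OntologyTree],
                         matrices: MatrixBank | Iterable[ClosenessMatrix],
                         matcher: str = "greedy",
                         graph: ContractionGraph | None = None
                         ) -> IntegratedOntology:
    """k - 1 max-edge contractions over stale pairwise cohesion scores.

    Pairwise maximum cohesion scores are computed once.  After contracting
    the heaviest edge (integrating its two units), the parallel edges to
    every other unit collapse to the maximum of the two stale weights --
    true weight increases only grow, so the stale maximum stays a valid
    lower bound and the final cohesion is at least the weight of the
    maximum spanning tree of the initial graph.

    A precomputed ``graph`` (from :func:`pairwise_score_graph`) may be
    passed to avoid recomputing the initial scores; it is consumed.
    """
    bank = _as_bank(matrices)
    if graph is None:
        graph = pairwise_score_graph(trees, matrices, matcher)
    while len(graph.units) > 1:
        k1, k2 = graph.max_edge()
        merged, _ = _integrate_units(graph.units.pop(k1),
                                     graph.units.pop(k2), bank, matcher)
        mk = _unit_key(merged)
        new_weights: dict[frozenset, float] = {}
        for pair, w in graph.weights.items():
            if k1 in pair and k2 in pair:
                continue
            if k1 in pair or k2 in pair:
                other = next(iter(pair - {k1, k2}))
                key = frozenset((mk, other))
                new_weights[key] = max(new_weights.get(key, 0.0), w)
            else:
                new_weights[pair] = w
        graph.weights = new_weights
        graph.units[mk] = merged
    return next(iter(graph.units.values()))
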