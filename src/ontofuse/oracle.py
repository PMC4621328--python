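"""Independent brute-force optima and the LCA-preservation validator.

Nothing here shares code with the production DP: the point of this module
is to provide slow but trustworthy ground truth for tests and acceptance
checks.  Two independent pairwise oracles are provided (a forest recursion
with exhaustively enumerated matchings, and a direct enumeration of merge
mappings), because agreement of two differently-derived oracles is the
strongest available guard against a shared systematic error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx

from .core import ClosenessMatrix, MatrixBank, OntologyError, OntologyTree
from .multi import ContractionGraph
from .pairwise import IntegratedOntology

__all__ = [
    "ViolationReport", "exhaustive_multi_optimum", "exhaustive_pair_optimum",
    "mapping_pair_optimum", "max_spanning_tree_weight", "validate_lca_preservation",
]


# ---------------------------------------------------------------------------
# LCA-preservation validator
# ---------------------------------------------------------------------------

@dataclass
class ViolationReport:
    """LCA-preservation violations found in an integrated ontology.

    Each violation records (ontology_id, term x, term y, source LCA,
    members of the merged LCA node).  An empty list means the integration
    preserves every source ontology's LCA structure.
    """

    violations: list[tuple[str, str, str, str, tuple[tuple[str, str], ...]]] \
        = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy iff there ARE violations
        return bool(self.violations)

    def __len__(self) -> int:
        return len(self.violations)


class _NodeLCA:
    """Binary-lifting LCA over the merged node tree."""

    def __init__(self, onto: IntegratedOntology):
        n = len(onto.nodes)
        self.depth = onto.depths()
        logn = max(1, (max(self.depth) + 1).bit_length())
        up = [[0] * n for _ in range(logn)]
        for i, nd in enumerate(onto.nodes):
            up[0][i] = nd.parent if i else 0
        for lvl in range(1, logn):
            prev = up[lvl - 1]
            cur = up[lvl]
            for i in range(n):
                cur[i] = prev[prev[i]]
        self.up = up

    def lca(self, a: int, b: int) -> int:
        depth, up = self.depth, self.up
        if depth[a] < depth[b]:
            a, b = b, a
        diff = depth[a] - depth[b]
        lvl = 0
        while diff:
            if diff & 1:
                a = up[lvl][a]
            diff >>= 1
            lvl += 1
        if a == b:
            return a
        for lvl in range(len(up) - 1, -1, -1):
            if up[lvl][a] != up[lvl][b]:
                a = up[lvl][a]
                b = up[lvl][b]
        return up[0][a]


def validate_lca_preservation(onto: IntegratedOntology,
                        sources: Iterable[OntologyTree]) -> ViolationReport:
    """Exhaustively check LCA preservation for every within-ontology pair.

    For every pair of terms x, y of one source tree, the source LCA term
    must be a member of the lowest common ancestor node of the merged
    images of x and y.  All O(sum n_i^2) pairs are checked.
    """
    report = ViolationReport()
    lifter = _NodeLCA(onto)
    for tree in sources:
        ont = tree.ontology_id
        node_at = []
        for v in range(tree.n + 1):
            if v == 0:
                node_at.append(0)
                continue
            key = (ont, tree.ids[v])
            if key not in onto.node_of:
                raise OntologyError(f"vertex {key} missing from integration")
            node_at.append(onto.node_of[key])
        # Enumerate pairs grouped by their source LCA: for each vertex l,
        # pairs (l, descendant) and cross-child-subtree pairs have LCA l.
        subtrees = [tree.subtree_indices(tree.ids[v]) if v else []
                    for v in range(tree.n + 1)]

        def check(x: int, y: int, l: int) -> None:
            nl = lifter.lca(node_at[x], node_at[y])
            members = onto.nodes[nl].members
            if (ont, tree.ids[l]) not in members:
                report.violations.append(
                    (ont, tree.ids[x], tree.ids[y], tree.ids[l], members))

        for l in range(1, tree.n + 1):
            kids = tree.children[l]
            for c in kids:
                for d in subtrees[c]:
                    check(l, d, l)
            for c1, c2 in combinations(kids, 2):
                for d1 in subtrees[c1]:
                    for d2 in subtrees[c2]:
                        check(d1, d2, l)
    return report


# ---------------------------------------------------------------------------
# Oracle 1: forest recursion with exhaustive matchings
# ---------------------------------------------------------------------------

def exhaustive_pair_optimum(t_a: OntologyTree, t_b: OntologyTree,
                            m: ClosenessMatrix, limit: int = 7) -> float:
    """True optimal pairwise cohesion by recursive exhaustive search.

    Recurses on (merge roots + enumerate every matching of the child
    forests) versus (drop one root), with memoisation.  Guarded to trees of
    at most ``limit`` vertices each.
    """
    if t_a.n > limit or t_b.n > limit:
        raise OntologyError(f"oracle size guard exceeded "
                            f"({t_a.n}x{t_b.n} > {limit})")
    M = m.dense(t_a, t_b)
    ch_a, ch_b = t_a.children, t_b.children
    pair_memo: dict[tuple[int, int], float] = {}
    forest_memo: dict[tuple[tuple[int, ...], tuple[int, ...]], float] = {}

    def g_pair(x: int, y: int) -> float:
        key = (x, y)
        if key in pair_memo:
            return pair_memo[key]
        best = M[x, y] + g_forest(tuple(ch_a[x]), tuple(ch_b[y]))
        for y2 in ch_b[y]:
            best = max(best, g_pair(x, y2))
        for x2 in ch_a[x]:
            best = max(best, g_pair(x2, y))
        pair_memo[key] = best
        return best

    def g_forest(fa: tuple[int, ...], fb: tuple[int, ...]) -> float:
        if not fa or not fb:
            return 0.0
        key = (fa, fb)
        if key in forest_memo:
            return forest_memo[key]
        head, rest = fa[0], fa[1:]
        best = g_forest(rest, fb)  # head matched with nothing
        for idx, y in enumerate(fb):
            remaining = fb[:idx] + fb[idx + 1:]
            best = max(best, g_pair(head, y) + g_forest(rest, remaining))
        forest_memo[key] = best
        return best

    return float(g_pair(1, 1))


# ---------------------------------------------------------------------------
# Oracle 2: direct enumeration of merge mappings
# ---------------------------------------------------------------------------

def mapping_pair_optimum(t_a: OntologyTree, t_b: OntologyTree,
                         m: ClosenessMatrix, limit: int = 7) -> float:
    """Optimal pairwise cohesion by enumerating merge mappings directly.

    A set of merged pairs is realizable as an LCA-preserving tree iff the
    induced partial injection A -> B (a) preserves ancestor order and
    incomparability in both directions and (b) is closed under LCA: if
    (a1, b1) and (a2, b2) are merged, so is (lca(a1, a2), lca(b1, b2)).
    This characterisation is derived independently of the forest recursion
    and is cross-validated against it in the test suite.
    """
    if t_a.n > limit or t_b.n > limit:
        raise OntologyError(f"oracle size guard exceeded "
                            f"({t_a.n}x{t_b.n} > {limit})")
    M = m.dense(t_a, t_b)
    n, mm = t_a.n, t_b.n
    anc_a = [[t_a.is_ancestor(i, j) for j in range(n + 1)]
             for i in range(n + 1)]
    anc_b = [[t_b.is_ancestor(i, j) for j in range(mm + 1)]
             for i in range(mm + 1)]
    lca_a = [[0] * (n + 1)] + [
        [0] + [t_a.idx(t_a.lca(t_a.ids[i], t_a.ids[j]))
               for j in range(1, n + 1)] for i in range(1, n + 1)]
    lca_b = [[0] * (mm + 1)] + [
        [0] + [t_b.idx(t_b.lca(t_b.ids[i], t_b.ids[j]))
               for j in range(1, mm + 1)] for i in range(1, mm + 1)]

    best = 0.0
    assigned: list[tuple[int, int]] = []
    mapped: dict[int, int] = {}

    def closure_ok() -> bool:
        for (a1, b1), (a2, b2) in combinations(assigned, 2):
            if mapped.get(lca_a[a1][a2]) != lca_b[b1][b2]:
                return False
        return True

    def order_ok(a: int, b: int) -> bool:
        for a2, b2 in assigned:
            down = anc_a[a][a2]
            up = anc_a[a2][a]
            if (down, up) != (anc_b[b][b2], anc_b[b2][b]):
                return False
        return True

    def recurse(a: int, used_b: set[int], acc: float) -> None:
        nonlocal best
        if a > n:
            if acc > best and closure_ok():
                best = acc
            return
        recurse(a + 1, used_b, acc)  # a stays a singleton
        for b in range(1, mm + 1):
            if b in used_b or not order_ok(a, b):
                continue
            assigned.append((a, b))
            mapped[a] = b
            used_b.add(b)
            recurse(a + 1, used_b, acc + M[a, b])
            used_b.discard(b)
            del mapped[a]
            assigned.pop()

    recurse(1, set(), 0.0)
    return float(best)


# ---------------------------------------------------------------------------
# Multi-ontology exhaustive optimum
# ---------------------------------------------------------------------------

def exhaustive_multi_optimum(trees: Sequence[OntologyTree],
                             matrices: MatrixBank | Iterable[ClosenessMatrix],
                             max_k: int = 3, max_n: int = 4) -> float:
    """True optimal multi-way cohesion by exhaustive grouping recursion.

    Generalises the pairwise forest recursion: given one forest per
    ontology, the trees are partitioned into merged subtrees holding at
    most one tree per source forest; inside each group, every non-empty
    subset of the roots may form the top node, the rest descending intact.
    Guarded to ``max_k`` ontologies of ``max_n`` vertices each.
    """
    bank = matrices if isinstance(matrices, MatrixBank) else MatrixBank(matrices)
    k = len(trees)
    if k < 2:
        raise OntologyError("need at least two ontologies")
    if k > max_k or any(t.n > max_n for t in trees):
        raise OntologyError(f"oracle size guard exceeded (k={k}, "
                            f"n={[t.n for t in trees]})")
    dense: dict[tuple[int, int], "np.ndarray"] = {}
    import numpy as np  # local: only needed for the dense tables
    for i in range(k):
        for j in range(i + 1, k):
            dense[(i, j)] = bank.matrix(
                trees[i].ontology_id, trees[j].ontology_id
            ).dense(trees[i], trees[j])

    def cross(items: Sequence[tuple[int, int]]) -> float:
        total = 0.0
        for (oi, u), (oj, v) in combinations(sorted(items), 2):
            if oi != oj:
                total += dense[(oi, oj)][u, v]
        return total

    State = tuple[tuple[int, ...], ...]
    g_memo: dict[State, float] = {}
    t_memo: dict[tuple[tuple[int, int], ...], float] = {}

    def g_forests(state: State) -> float:
        items = [(oi, v) for oi, roots in enumerate(state) for v in roots]
        if len(items) <= 1:
            return 0.0
        if state in g_memo:
            return g_memo[state]
        pivot = items[0]
        oi, _ = pivot
        others = [o for o in range(k) if o != oi and state[o]]
        best = 0.0

        def enum_groups(pos: int, group: list[tuple[int, int]]) -> None:
            nonlocal best
            if pos == len(others):
                rest = tuple(
                    tuple(v for v in roots
                          if (o, v) not in group and (o, v) != pivot)
                    for o, roots in enumerate(state))
                val = t_group(tuple(sorted(group + [pivot]))) + g_forests(rest)
                if val > best:
                    best = val
                return
            enum_groups(pos + 1, group)  # skip this ontology
            o = others[pos]
            for v in state[o]:
                group.append((o, v))
                enum_groups(pos + 1, group)
                group.pop()

        enum_groups(0, [])
        g_memo[state] = best
        return best

    def t_group(group: tuple[tuple[int, int], ...]) -> float:
        """Best cohesion of one merged subtree built from these trees."""
        if len(group) == 1:
            return 0.0
        if group in t_memo:
            return t_memo[group]
        best = 0.0
        n_g = len(group)
        for mask in range(1, 1 << n_g):
            top = [group[i] for i in range(n_g) if mask >> i & 1]
            state = [()] * k
            for oi, v in group:
                if (oi, v) in top:
                    state[oi] = tuple(trees[oi].children[v])
                else:
                    state[oi] = (v,)
            val = cross(top) + g_forests(tuple(state))
            if val > best:
                best = val
        t_memo[group] = best
        return best

    roots: State = tuple((1,) for _ in range(k))
    return float(g_forests(roots))


def max_spanning_tree_weight(
        g: ContractionGraph | dict[frozenset, float]) -> float:
    """Weight of the maximum spanning tree of a contraction graph."""
    weights = g.weights if isinstance(g, ContractionGraph) else g
    graph = nx.Graph()
    for pair, w in weights.items():
        a, b = sorted(pair)
        graph.add_edge(a, b, weight=w)
    if graph.number_of_nodes() < 2:
        raise OntologyError("need at least two nodes for a spanning tree")
    if not nx.is_connected(graph):
        raise OntologyError("contraction graph must be connected")
    mst = nx.maximum_spanning_tree(graph)
    return float(sum(d["weight"] for _, _, d in mst.edges(data=True)))
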