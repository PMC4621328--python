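"""Pairwise ontology integration: cohesion DP, reconstruction, heuristic.

The objective is the *cohesion* of the merged tree: the sum over merged
nodes of the closeness of the term pairs they co-locate.  Integration must
preserve each source ontology's lowest-common-ancestor structure: for any
two terms of one source, their source LCA must sit in the LCA node of their
merged images.

The optimal value g(T_A, T_B) obeys a divide-and-conquer recurrence over
root merging: either the two roots merge (collect their closeness, then
optimally match the two child forests subtree-against-subtree), or one root
stays out and the other whole tree descends into one of its child subtrees.
Filling a (n+1) x (m+1) cohesion matrix in reverse topological order over
both trees therefore yields the optimum at entry (0, 0), where index 0 is
each tree's virtual root.  With the optimal (assignment) matching kernel
the DP is exact; with the greedy maximal kernel it runs in O(n^2 log n)
overall and empirically retains at least half the optimal cohesion.

Reconstruction replays the DP decisions top-down from entry (0, 0) instead
of storing them (storing every matching would cost O(n^3) memory).  This
relies on the matching kernels being deterministic: the same edge weights
always produce the same pairs.

The heuristic integrator is a single top-down greedy pass that picks, for
each vertex of T_A, the allowable T_B candidate maximizing
closeness / beta^rdepth, where rdepth penalises candidates far below the
shallowest still-allowable vertex.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import ClosenessMatrix, MatrixBank, OntologyError, OntologyTree

__all__ = [
    "CohesionMatrix", "HeuristicConfig", "IntegratedOntology", "MergedNode",
    "build_cohesion_matrix", "build_integrated_ontology", "cohesion_of",
    "heuristic_integrate",
]


# ---------------------------------------------------------------------------
# Integrated ontology container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MergedNode:
    """One node of an integrated ontology.

    ``members`` holds (ontology_id, term_id) pairs, at most one per source
    ontology; the root (merged virtual roots) and pass-through nodes created
    when units are stacked have no members.  ``weight`` is the summed
    pairwise closeness of the members.
    """

    members: tuple[tuple[str, str], ...]
    parent: int | None
    weight: float


class IntegratedOntology:
    """A merged tree whose nodes contain vertices from one or more sources.

    Every vertex of every source ontology appears in exactly one node;
    vertices that found no partner occupy singleton nodes of weight 0.  The
    total cohesion is the sum of node weights.
    """

    def __init__(self, nodes: Sequence[MergedNode], total_cohesion: float,
                 ontology_ids: Iterable[str]):
        self.nodes: list[MergedNode] = list(nodes)
        if not self.nodes or self.nodes[0].parent is not None:
            raise OntologyError("node 0 must be the parentless root")
        self.total_cohesion = float(total_cohesion)
        self.ontology_ids: tuple[str, ...] = tuple(sorted(set(ontology_ids)))
        self.node_of: dict[tuple[str, str], int] = {}
        for i, node in enumerate(self.nodes):
            if i > 0 and not 0 <= node.parent < i:  # type: ignore[operator]
                raise OntologyError("node parents must precede children")
            onts = [o for o, _ in node.members]
            if len(set(onts)) != len(onts):
                raise OntologyError(
                    f"node {i} holds two vertices of one ontology")
            for member in node.members:
                if member in self.node_of:
                    raise OntologyError(f"vertex {member} appears twice")
                self.node_of[member] = i

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def merged_pairs(self) -> int:
        """Number of nodes containing two or more source vertices."""
        return sum(1 for nd in self.nodes if len(nd.members) > 1)

    def depths(self) -> list[int]:
        d = [0] * len(self.nodes)
        for i, nd in enumerate(self.nodes):
            if i:
                d[i] = d[nd.parent] + 1  # type: ignore[index]
        return d

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in self.nodes]
        for i, nd in enumerate(self.nodes):
            if i:
                ch[nd.parent].append(i)  # type: ignore[index]
        return ch

    @classmethod
    def from_tree(cls, tree: OntologyTree) -> "IntegratedOntology":
        """Lift a source tree: virtual-root node plus one singleton per term."""
        nodes = [MergedNode((), None, 0.0)]
        for v in range(1, tree.n + 1):
            nodes.append(MergedNode(((tree.ontology_id, tree.ids[v]),),
                                    tree.parent[v], 0.0))
        return cls(nodes, 0.0, [tree.ontology_id])


def cohesion_of(onto: IntegratedOntology,
                matrices: MatrixBank | Iterable[ClosenessMatrix]) -> float:
    """Recompute total cohesion from scratch from the closeness matrices.

    Never reads cached node weights; used as a consistency cross-check
    against the cohesion matrix entry (0, 0).
    """
    bank = matrices if isinstance(matrices, MatrixBank) else MatrixBank(matrices)
    total = 0.0
    for node in onto.nodes:
        ms = node.members
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                (oa, a), (ob, b) = ms[i], ms[j]
                total += bank.get(oa, a, ob, b)
    return total


# ---------------------------------------------------------------------------
# Matching kernels specialised for DP cells (index lists + score table)
# ---------------------------------------------------------------------------

def _greedy_cell(ca: list[int], cb: list[int], g: np.ndarray
                 ) -> tuple[float, list[tuple[int, int]]]:
    edges = []
    for x in ca:
        gx = g[x]
        for y in cb:
            w = gx[y]
            if w > 0.0:
                edges.append((w, x, y))
    if not edges:
        return 0.0, []
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))
    used_l: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[int, int]] = []
    total = 0.0
    for w, x, y in edges:
        if x not in used_l and y not in used_r:
            used_l.add(x)
            used_r.add(y)
            pairs.append((x, y))
            total += w
    return total, pairs


def _optimal_cell(ca: list[int], cb: list[int], g: np.ndarray
                  ) -> tuple[float, list[tuple[int, int]]]:
    if len(ca) == 1 and len(cb) == 1:
        w = g[ca[0], cb[0]]
        return (float(w), [(ca[0], cb[0])]) if w > 0.0 else (0.0, [])
    sub = g[np.ix_(ca, cb)]
    rows, cols = linear_sum_assignment(sub, maximize=True)
    total = float(sub[rows, cols].sum())
    pairs = [(ca[r], cb[c]) for r, c in zip(rows, cols) if sub[r, c] > 0.0]
    return total, pairs


_CELL_MATCHERS: dict[str, Callable] = {
    "greedy": _greedy_cell,
    "optimal": _optimal_cell,
}


# ---------------------------------------------------------------------------
# Cohesion matrix (bottom-up DP)
# ---------------------------------------------------------------------------

class CohesionMatrix:
    """Table of optimal subtree-pair cohesion scores.

    ``table[i, j]`` is the best cohesion achievable when integrating the
    subtree of T_A rooted at index ``i`` with the subtree of T_B rooted at
    index ``j``; index 0 is the virtual root, so ``table[0, 0]`` is the
    whole-problem optimum (exact with the optimal kernel).
    """

    def __init__(self, table: np.ndarray, matcher: str, t_a: OntologyTree,
                 t_b: OntologyTree, closeness_dense: np.ndarray):
        self.table = table
        self.matcher = matcher
        self.t_a = t_a
        self.t_b = t_b
        self.closeness_dense = closeness_dense

    @property
    def value(self) -> float:
        """Maximum cohesion score of the full integration (entry (0, 0))."""
        return float(self.table[0, 0])

    def entry(self, a: str | int, b: str | int) -> float:
        return float(self.table[self.t_a.idx(a), self.t_b.idx(b)])


def build_cohesion_matrix(t_a: OntologyTree, t_b: OntologyTree,
                          m: ClosenessMatrix,
                          matcher: str = "greedy") -> CohesionMatrix:
    """Fill the cohesion matrix bottom-up (reverse topological order).

    Each entry (i, j) is the maximum of three candidates: merge the two
    subtree roots and optimally match their child forests; keep i's subtree
    whole and descend into one child of j; or the symmetric case.  Child
    forests enter the matching with the already-computed entries as edge
    weights, so the amortised matching cost over the whole table is
    O(n * m) edge visits.
    """
    if matcher not in _CELL_MATCHERS:
        raise OntologyError(f"unknown matcher {matcher!r}")
    match_cell = _CELL_MATCHERS[matcher]
    closeness = m.dense(t_a, t_b)  # validates sides, scores, terms
    n, mm = t_a.n, t_b.n
    g = np.zeros((n + 1, mm + 1))
    ch_a, ch_b = t_a.children, t_b.children
    for i in range(n, -1, -1):
        ca = ch_a[i]
        Mi = closeness[i]
        gi = g[i]
        for j in range(mm, -1, -1):
            cb = ch_b[j]
            best = Mi[j]
            if ca and cb:
                best = best + match_cell(ca, cb, g)[0]
            if cb:
                sa = max(gi[y] for y in cb)
                if sa > best:
                    best = sa
            if ca:
                sb = max(g[x, j] for x in ca)
                if sb > best:
                    best = sb
            gi[j] = best
    return CohesionMatrix(g, matcher, t_a, t_b, closeness)


# ---------------------------------------------------------------------------
# Reconstruction (top-down replay of the DP)
# ---------------------------------------------------------------------------

def _attach_subtree(nodes: list[MergedNode], tree: OntologyTree, top: int,
                    parent_idx: int) -> None:
    """Attach the source subtree rooted at index ``top`` as singleton nodes."""
    queue = deque([(top, parent_idx)])
    while queue:
        v, pidx = queue.popleft()
        nodes.append(MergedNode(((tree.ontology_id, tree.ids[v]),), pidx, 0.0))
        nidx = len(nodes) - 1
        for c in tree.children[v]:
            queue.append((c, nidx))


def build_integrated_ontology(cm: CohesionMatrix,
                              t_a: OntologyTree | None = None,
                              t_b: OntologyTree | None = None,
                              m: ClosenessMatrix | None = None,
                              matcher: str | None = None
                              ) -> IntegratedOntology:
    """Reconstruct an optimal integrated tree from a cohesion matrix.

    Works breadth-first with a queue of (i, j, parent-node) triples starting
    at (0, 0).  At each triple the three DP candidates are recomputed with
    the same kernel and the same tie-breaks, and the first one (in the fixed
    order merge > descend-into-B > descend-into-A) that reproduces the
    stored entry is taken.  Exact float equality is legitimate here because
    identical arithmetic is replayed.
    """
    t_a = t_a if t_a is not None else cm.t_a
    t_b = t_b if t_b is not None else cm.t_b
    if t_a is not cm.t_a or t_b is not cm.t_b:
        if (t_a.ontology_id, t_b.ontology_id) != (cm.t_a.ontology_id,
                                                  cm.t_b.ontology_id):
            raise OntologyError("trees do not match the cohesion matrix")
    if matcher is not None and matcher != cm.matcher:
        raise OntologyError(
            f"matrix built with {cm.matcher!r} but reconstruction requested "
            f"{matcher!r}; matchings would not replay identically")
    match_cell = _CELL_MATCHERS[cm.matcher]
    closeness = cm.closeness_dense
    g = cm.table
    ch_a, ch_b = t_a.children, t_b.children
    ia, ib = t_a.ontology_id, t_b.ontology_id

    nodes: list[MergedNode] = [MergedNode((), None, 0.0)]
    queue: deque[tuple[int, int, int]] = deque([(0, 0, 0)])
    while queue:
        i, j, pidx = queue.popleft()
        ca, cb = ch_a[i], ch_b[j]
        target = g[i, j]
        if ca and cb:
            mtotal, pairs = match_cell(ca, cb, g)
        else:
            mtotal, pairs = 0.0, []
        if closeness[i, j] + mtotal == target:
            # Case 1: merge the two subtree roots.
            if i == 0 and j == 0:
                nidx = 0
            else:
                members = tuple(
                    mem for mem in (((ia, t_a.ids[i]),) if i else ()) +
                    (((ib, t_b.ids[j]),) if j else ()))
                nodes.append(MergedNode(members, pidx,
                                        float(closeness[i, j])))
                nidx = len(nodes) - 1
            matched_a = {x for x, _ in pairs}
            matched_b = {y for _, y in pairs}
            for x, y in pairs:
                queue.append((x, y, nidx))
            for x in ca:
                if x not in matched_a:
                    _attach_subtree(nodes, t_a, x, nidx)
            for y in cb:
                if y not in matched_b:
                    _attach_subtree(nodes, t_b, y, nidx)
            continue
        hit = next((y for y in cb if g[i, y] == target), None)
        if hit is not None:
            # Case 2: keep subtree i whole, j's root stays unmatched above.
            if j == 0:
                nidx = pidx
            else:
                nodes.append(MergedNode(((ib, t_b.ids[j]),), pidx, 0.0))
                nidx = len(nodes) - 1
            queue.append((i, hit, nidx))
            for y in cb:
                if y != hit:
                    _attach_subtree(nodes, t_b, y, nidx)
            continue
        hit = next((x for x in ca if g[x, j] == target), None)
        if hit is not None:
            # Case 3: symmetric descent into A.
            if i == 0:
                nidx = pidx
            else:
                nodes.append(MergedNode(((ia, t_a.ids[i]),), pidx, 0.0))
                nidx = len(nodes) - 1
            queue.append((hit, j, nidx))
            for x in ca:
                if x != hit:
                    _attach_subtree(nodes, t_a, x, nidx)
            continue
        raise OntologyError(
            f"no DP case reproduces entry ({i}, {j}); cohesion matrix and "
            "matcher are inconsistent (nondeterministic matching?)")

    return IntegratedOntology(nodes, float(g[0, 0]), [ia, ib])


def integrate_pair(t_a: OntologyTree, t_b: OntologyTree, m: ClosenessMatrix,
                   matcher: str = "greedy") -> IntegratedOntology:
    """Convenience wrapper: cohesion DP followed by reconstruction."""
    return build_integrated_ontology(build_cohesion_matrix(t_a, t_b, m,
                                                           matcher))


# ---------------------------------------------------------------------------
# Heuristic top-down integration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeuristicConfig:
    """Depth-regularisation setting for the heuristic integrator.

    ``beta`` >= 1 is the base of the rdepth penalty: a candidate sitting
    ``d`` levels below the shallowest allowable candidate is scored
    closeness / beta**d.  ``beta == 1`` disables depth weighting; very large
    values restrict choices to the shallowest allowable candidates.
    """

    beta: float = 1.0

    def __post_init__(self):
        if not self.beta >= 1.0:
            raise OntologyError(f"beta must be >= 1, got {self.beta}")


def heuristic_integrate(t_a: OntologyTree, t_b: OntologyTree,
                        m: ClosenessMatrix,
                        cfg: HeuristicConfig | float = HeuristicConfig()
                        ) -> IntegratedOntology:
    """Single-pass greedy integration with the beta^rdepth selection rule.

    T_A is walked top-down (BFS).  Each vertex may merge with an *allowable*
    T_B vertex: a descendant of its nearest merged ancestor's partner that
    has not been claimed by a sibling branch.  Claiming is exclusive per
    top-level subtree of the partner's child forest -- once one child branch
    of a merged vertex reaches into a subtree, no other branch may use any
    vertex of that subtree (otherwise two incomparable branches would share
    a B-side common ancestor and break LCA preservation).  A merge happens
    only for strictly positive closeness.
    """
    if not isinstance(cfg, HeuristicConfig):
        cfg = HeuristicConfig(float(cfg))
    beta = cfg.beta
    closeness = m.dense(t_a, t_b)
    ia, ib = t_a.ontology_id, t_b.ontology_id

    # Precompute, per B vertex, its subtree's vertex list (claim removal).
    nodes: list[MergedNode] = [MergedNode((), None, 0.0)]
    node_of_a: dict[int, int] = {0: 0}
    node_of_b: dict[int, int] = {0: 0}
    # pool_of[a]: the mutable set of available B subtree roots that a's
    # children draw from.  Singleton vertices share their parent's pool.
    pool_of: dict[int, set[int]] = {0: set(t_b.children[0])}
    total = 0.0

    for a in range(1, t_a.n + 1):
        p = t_a.parent[a]
        pool = pool_of[p]
        # Gather candidates: all vertices inside the available subtrees.
        best_b = -1
        best_score = 0.0
        if pool:
            candidates: list[int] = []
            stack = sorted(pool)
            min_depth = min(t_b.depth[r] for r in pool)
            queue = deque(stack)
            while queue:
                v = queue.popleft()
                candidates.append(v)
                queue.extend(t_b.children[v])
            Ma = closeness[a]
            for b in candidates:
                w = Ma[b]
                if w <= 0.0:
                    continue
                score = w / beta ** (t_b.depth[b] - min_depth)
                if score > best_score or (score == best_score and
                                          (best_b == -1 or b < best_b)):
                    best_score = score
                    best_b = b
        if best_b >= 0:
            b = best_b
            # Claim the available subtree containing b: walk up to the
            # highest unplaced ancestor-or-self, which is a pool root.
            r_claim = b
            while t_b.parent[r_claim] not in node_of_b:
                r_claim = t_b.parent[r_claim]
            pool.discard(r_claim)
            # Place the singleton chain of b's unplaced strict ancestors
            # (r_claim .. parent(b)) under a's parent node.
            cur = node_of_a[p]
            chain = []
            v = t_b.parent[b]
            while v != t_b.parent[r_claim]:
                chain.append(v)
                v = t_b.parent[v]
            for v in reversed(chain):
                nodes.append(MergedNode(((ib, t_b.ids[v]),), cur, 0.0))
                cur = len(nodes) - 1
                node_of_b[v] = cur
            w = float(closeness[a, b])
            nodes.append(MergedNode(((ia, t_a.ids[a]), (ib, t_b.ids[b])),
                                    cur, w))
            nidx = len(nodes) - 1
            node_of_a[a] = nidx
            node_of_b[b] = nidx
            pool_of[a] = set(t_b.children[b])
            total += w
        else:
            nodes.append(MergedNode(((ia, t_a.ids[a]),), node_of_a[p], 0.0))
            node_of_a[a] = len(nodes) - 1
            pool_of[a] = pool  # children share the parent's pool

    # Remaining B vertices become singletons preserving B's parent order.
    for b in range(1, t_b.n + 1):
        if b not in node_of_b:
            nodes.append(MergedNode(((ib, t_b.ids[b]),),
                                    node_of_b[t_b.parent[b]], 0.0))
            node_of_b[b] = len(nodes) - 1

    return IntegratedOntology(nodes, total, [ia, ib])
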