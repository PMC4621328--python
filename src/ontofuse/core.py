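"""Rooted-tree data model for hierarchical ontologies and term closeness.

An *ontology* here is a rooted tree of concept terms connected by
child->parent (is_a-like) edges, as found in GO, NDFRT, or any UMLS source
vocabulary whose MRHIER paths resolve to a tree.  DAG-shaped hierarchies must
be pre-expanded by the caller (duplicated concepts treated as independent
terms); :func:`build_tree` rejects anything that is not a tree.

Every tree exposes a *virtual super-root* at index 0 whose only child is the
real root and whose closeness to every term is zero.  This lets whole-tree
integration and root-vs-root integration share one recurrence, with the final
answer living at cohesion-matrix entry (0, 0).

Vertex indices are assigned breadth-first from the real root with
lexicographic tie-breaking among siblings, so they are dense (1..n), children
always carry larger indices than their parents, and every run of every
algorithm is reproducible.
"""

from __future__ import annotations

import math
from collections import deque
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

#: Sentinel accepted by vertex-addressed operations to mean the virtual root.
VIRTUAL = 0


class OntologyError(ValueError):
    """Raised for structurally invalid trees, matrices, or integrations."""


class OntologyTree:
    """A rooted tree of ontology terms with dense breadth-first indices.

    Parameters
    ----------
    ontology_id:
        Short identifier of the source ontology (e.g. ``"GO"``).
    ids:
        Term identifier per index; ``ids[0]`` is ``None`` (virtual root).
    parent:
        Parent index per vertex; ``parent[real_root] == 0``.
    labels:
        Optional term-name mapping (term id -> human readable label).
    """

    __slots__ = ("ontology_id", "ids", "index", "parent", "children", "depth",
                 "labels")

    def __init__(self, ontology_id: str, ids: Sequence[str | None],
                 parent: Sequence[int],
                 labels: Mapping[str, str] | None = None):
        self.ontology_id = str(ontology_id)
        self.ids: list[str | None] = list(ids)
        self.parent: list[int] = list(parent)
        n = len(self.ids) - 1
        if n < 1:
            raise OntologyError("a tree needs at least one real vertex")
        self.index: dict[str, int] = {}
        for i in range(1, n + 1):
            t = self.ids[i]
            if t in self.index:
                raise OntologyError(f"duplicate term identifier {t!r}")
            self.index[t] = i
        children: list[list[int]] = [[] for _ in range(n + 1)]
        depth = [0] * (n + 1)
        depth[0] = -1
        for v in range(1, n + 1):
            p = self.parent[v]
            if not 0 <= p < v:
                raise OntologyError("parent indices must precede children")
            children[p].append(v)
            depth[v] = depth[p] + 1
        self.children = children
        self.depth = depth
        self.labels = dict(labels) if labels else {}

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        """Number of real vertices."""
        return len(self.ids) - 1

    @property
    def root(self) -> str:
        """Identifier of the real root term."""
        return self.ids[1]  # type: ignore[return-value]

    def idx(self, term: str | int) -> int:
        """Resolve a term id (or the ``VIRTUAL`` sentinel) to its index."""
        if term == VIRTUAL:
            return VIRTUAL
        try:
            return self.index[term]  # type: ignore[index]
        except KeyError:
            raise OntologyError(
                f"unknown term {term!r} in ontology {self.ontology_id!r}")

    def term(self, i: int) -> str | None:
        return self.ids[i]

    def terms(self) -> list[str]:
        """All real term identifiers in index order."""
        return self.ids[1:]  # type: ignore[return-value]

    # -- structural operations --------------------------------------------

    def reverse_topological_order(self) -> list[str]:
        """Real terms ordered so that every vertex precedes its ancestors.

        Because indices are breadth-first, this is simply the reverse of the
        index order; its reverse is a valid top-down order.
        """
        return [self.ids[i] for i in range(self.n, 0, -1)]  # type: ignore

    def lca(self, x: str | int, y: str | int) -> str:
        """Lowest common ancestor (ancestor-or-self) of two terms."""
        i, j = self.idx(x), self.idx(y)
        if i == VIRTUAL or j == VIRTUAL:
            raise OntologyError("lca is defined on real vertices only")
        while i != j:
            if self.depth[i] >= self.depth[j]:
                i = self.parent[i]
            else:
                j = self.parent[j]
        return self.ids[i]  # type: ignore[return-value]

    def children_forest(self, v: str | int) -> list[str]:
        """Roots of the subtrees left after deleting ``v`` from its subtree.

        For the virtual root this is ``[real root]``; for a leaf it is empty.
        Order is deterministic (ascending vertex index).
        """
        return [self.ids[c] for c in self.children[self.idx(v)]]  # type: ignore

    def subtree_indices(self, v: str | int) -> list[int]:
        """Indices of ``v`` and all of its descendants (BFS order)."""
        start = self.idx(v)
        out = [start] if start != VIRTUAL else []
        queue = deque(self.children[start])
        while queue:
            u = queue.popleft()
            out.append(u)
            queue.extend(self.children[u])
        return out

    def is_ancestor(self, a: int, d: int) -> bool:
        """True if index ``a`` is an ancestor-or-self of index ``d``."""
        while self.depth[d] > self.depth[a]:
            d = self.parent[d]
        return a == d

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"OntologyTree({self.ontology_id!r}, n={self.n})"


def build_tree(edges: Iterable[tuple[str, str]], ontology_id: str,
               root: str | None = None,
               labels: Mapping[str, str] | None = None) -> OntologyTree:
    """Build a validated :class:`OntologyTree` from (child, parent) pairs.

    Vertex indices are assigned breadth-first from the root, breaking ties
    between siblings lexicographically, so the same edge set always yields
    the same indexing regardless of input order.

    Raises :class:`OntologyError` on duplicate children (a vertex with two
    parents, i.e. DAG input), cycles, multiple roots, or empty input without
    a declared ``root``.
    """
    parent_of: dict[str, str] = {}
    nodes: set[str] = set()
    for child, par in edges:
        child, par = str(child), str(par)
        if child == par:
            raise OntologyError(f"self-loop at {child!r}: cycle detected")
        if child in parent_of:
            if parent_of[child] != par:
                raise OntologyError(
                    f"duplicate child {child!r} with two parents "
                    "(DAG input must be pre-expanded)")
            continue
        parent_of[child] = par
        nodes.add(child)
        nodes.add(par)
    if root is not None:
        nodes.add(str(root))
    if not nodes:
        raise OntologyError("no edges and no declared root")
    roots = sorted(nodes - set(parent_of))
    if len(roots) > 1:
        raise OntologyError(f"multiple roots: {roots}")
    if not roots:
        raise OntologyError("cycle detected: no root vertex")
    if root is not None and str(root) != roots[0]:
        raise OntologyError(
            f"declared root {root!r} does not match derived root {roots[0]!r}")

    kids: dict[str, list[str]] = {}
    for c, p in parent_of.items():
        kids.setdefault(p, []).append(c)
    for v in kids.values():
        v.sort()

    ids: list[str | None] = [None]
    parent_idx: list[int] = [-1]
    pos: dict[str, int] = {}
    queue = deque([(roots[0], 0)])
    while queue:
        term, pidx = queue.popleft()
        ids.append(term)
        parent_idx.append(pidx)
        pos[term] = len(ids) - 1
        for child in kids.get(term, ()):
            queue.append((child, pos[term]))
    if len(pos) != len(nodes):
        raise OntologyError("cycle detected: unreachable vertices "
                            f"{sorted(nodes - set(pos))}")
    return OntologyTree(ontology_id, ids, parent_idx, labels=labels)


class ClosenessMatrix:
    """Sparse non-negative closeness scores between two term sets.

    Entries absent from the matrix score 0, as does any query involving the
    virtual root of either side.  Scores must be finite and >= 0; the matrix
    is validated on construction.

    Two storage backends are supported transparently: a ``{(a, b): score}``
    mapping (natural for hand-written fixtures and TSV files) and a dense
    array with id maps (natural for synthetic benchmarks and merged-unit
    matrices, where every cross pair carries a score).
    """

    __slots__ = ("side_a", "side_b", "_map", "_arr", "_rows", "_cols")

    def __init__(self, side_a: str, side_b: str,
                 entries: Mapping[tuple[str, str], float] | None = None):
        self.side_a = str(side_a)
        self.side_b = str(side_b)
        self._arr = None
        self._rows: dict[str, int] | None = None
        self._cols: dict[str, int] | None = None
        self._map: dict[tuple[str, str], float] = {}
        if entries:
            for (a, b), s in entries.items():
                self._check_score(a, b, s)
                self._map[(str(a), str(b))] = float(s)

    @classmethod
    def from_array(cls, side_a: str, side_b: str, ids_a: Sequence[str],
                   ids_b: Sequence[str], array: np.ndarray) -> "ClosenessMatrix":
        array = np.asarray(array, dtype=float)
        if array.shape != (len(ids_a), len(ids_b)):
            raise OntologyError("closeness array shape mismatch")
        if not np.all(np.isfinite(array)) or np.any(array < 0):
            raise OntologyError("closeness scores must be finite and >= 0")
        obj = cls(side_a, side_b)
        obj._arr = array
        obj._rows = {str(t): i for i, t in enumerate(ids_a)}
        obj._cols = {str(t): i for i, t in enumerate(ids_b)}
        obj._map = None  # type: ignore[assignment]
        return obj

    @staticmethod
    def _check_score(a, b, s) -> None:
        if not math.isfinite(s) or s < 0:
            raise OntologyError(
                f"closeness({a!r}, {b!r}) = {s!r}: must be finite and >= 0")

    def get(self, a: str | int, b: str | int) -> float:
        """Score for a term pair; 0 for absent pairs or the virtual root."""
        if a == VIRTUAL or b == VIRTUAL:
            return 0.0
        if self._arr is not None:
            i = self._rows.get(str(a))  # type: ignore[union-attr]
            j = self._cols.get(str(b))  # type: ignore[union-attr]
            return float(self._arr[i, j]) if i is not None and j is not None else 0.0
        return self._map.get((str(a), str(b)), 0.0)

    def items(self) -> Iterator[tuple[str, str, float]]:
        """Iterate stored (term_a, term_b, score) triples."""
        if self._arr is not None:
            ra = {i: t for t, i in self._rows.items()}  # type: ignore[union-attr]
            rb = {j: t for t, j in self._cols.items()}  # type: ignore[union-attr]
            for i in range(self._arr.shape[0]):
                row = self._arr[i]
                for j in range(self._arr.shape[1]):
                    if row[j] != 0.0:
                        yield ra[i], rb[j], float(row[j])
        else:
            for (a, b), s in self._map.items():
                if s != 0.0:
                    yield a, b, s

    def transpose(self) -> "ClosenessMatrix":
        """The same scores with the two sides swapped."""
        if self._arr is not None:
            out = ClosenessMatrix(self.side_b, self.side_a)
            out._arr = self._arr.T
            out._rows, out._cols = dict(self._cols), dict(self._rows)  # type: ignore[arg-type]
            out._map = None  # type: ignore[assignment]
            return out
        return ClosenessMatrix(self.side_b, self.side_a,
                               {(b, a): s for (a, b), s in self._map.items()})

    def dense(self, t_a: OntologyTree, t_b: OntologyTree) -> np.ndarray:
        """(n+1) x (m+1) array indexed by the trees' vertex indices.

        Row/column 0 (virtual roots) are zero.  Raises on terms unknown to
        either tree and on a side/ontology mismatch.
        """
        if (self.side_a, self.side_b) != (t_a.ontology_id, t_b.ontology_id):
            raise OntologyError(
                f"matrix sides ({self.side_a!r}, {self.side_b!r}) do not match "
                f"trees ({t_a.ontology_id!r}, {t_b.ontology_id!r})")
        out = np.zeros((t_a.n + 1, t_b.n + 1))
        if self._arr is not None:
            rows = np.fromiter((t_a.idx(t) for t in self._rows), dtype=int,
                               count=len(self._rows))  # type: ignore[arg-type]
            cols = np.fromiter((t_b.idx(t) for t in self._cols), dtype=int,
                               count=len(self._cols))  # type: ignore[arg-type]
            out[np.ix_(rows, cols)] = self._arr
        else:
            for (a, b), s in self._map.items():
                out[t_a.idx(a), t_b.idx(b)] = s
        return out


class MatrixBank:
    """Lookup of pairwise closeness matrices keyed by unordered ontology pair."""

    def __init__(self, matrices: Iterable[ClosenessMatrix] = ()):
        self._by_pair: dict[frozenset[str], ClosenessMatrix] = {}
        for m in matrices:
            self.add(m)

    def add(self, m: ClosenessMatrix) -> None:
        key = frozenset((m.side_a, m.side_b))
        if len(key) != 2:
            raise OntologyError("a closeness matrix must relate two distinct "
                                f"ontologies, got {m.side_a!r}/{m.side_b!r}")
        if key in self._by_pair:
            raise OntologyError(f"duplicate matrix for pair {sorted(key)}")
        self._by_pair[key] = m

    def matrix(self, ont_a: str, ont_b: str) -> ClosenessMatrix:
        """Matrix oriented with ``ont_a`` on the left side."""
        m = self._by_pair.get(frozenset((ont_a, ont_b)))
        if m is None:
            raise OntologyError(f"missing closeness matrix for pair "
                                f"({ont_a!r}, {ont_b!r})")
        return m if m.side_a == ont_a else m.transpose()

    def has(self, ont_a: str, ont_b: str) -> bool:
        return frozenset((ont_a, ont_b)) in self._by_pair

    def get(self, ont_a: str, a: str, ont_b: str, b: str) -> float:
        """Closeness between term ``a`` of ``ont_a`` and ``b`` of ``ont_b``."""
        m = self._by_pair.get(frozenset((ont_a, ont_b)))
        if m is None:
            raise OntologyError(f"missing closeness matrix for pair "
                                f"({ont_a!r}, {ont_b!r})")
        if m.side_a == ont_a:
            return m.get(a, b)
        return m.get(b, a)

    def pairs(self) -> list[frozenset[str]]:
        return list(self._by_pair)

    def __iter__(self) -> Iterator[ClosenessMatrix]:
        return iter(self._by_pair.values())
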