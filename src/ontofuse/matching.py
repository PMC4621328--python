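"""Weighted bipartite matching kernels.

Subtree-pair integration reduces to repeated weighted bipartite matching
between child forests (each subtree on one side may merge with at most one
subtree on the other).  Three interchangeable kernels are provided:

``greedy``
    Heaviest-edge-first maximal matching.  Guarantees at least half the
    weight of the maximum matching and is the default in the integration
    pipeline because its amortised cost over a whole cohesion matrix is
    O(n^2 log n).
``optimal``
    Maximum weighted matching via the assignment algorithm
    (:func:`scipy.optimize.linear_sum_assignment`).
``exhaustive``
    Brute-force enumeration of all matchings; a test oracle only.

All kernels share one tie-break contract: edges are considered in order of
(weight descending, left item ascending, right item ascending) and
zero-weight edges never enter a matching (they add nothing to cohesion but
would constrain descendants).  The deterministic tie-break matters beyond
aesthetics: integrated-tree reconstruction replays matchings instead of
storing them, so two runs over the same inputs must pick identical pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Iterable

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import OntologyError

Item = Hashable


@dataclass(frozen=True)
class WeightedEdgeSet:
    """Edges of a weighted bipartite graph: (left, right, weight >= 0)."""

    edges: tuple[tuple[Item, Item, float], ...]

    def __init__(self, edges: Iterable[tuple[Item, Item, float]]):
        seen: set[tuple[Item, Item]] = set()
        clean = []
        for left, right, w in edges:
            if not math.isfinite(w) or w < 0:
                raise OntologyError(
                    f"edge ({left!r}, {right!r}) has invalid weight {w!r}")
            if (left, right) in seen:
                raise OntologyError(f"duplicate edge ({left!r}, {right!r})")
            seen.add((left, right))
            clean.append((left, right, float(w)))
        object.__setattr__(self, "edges", tuple(clean))

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class MatchingResult:
    """A matching (each item used at most once) and its total weight."""

    pairs: tuple[tuple[Item, Item], ...]
    total_weight: float


def _sorted_edges(edges: WeightedEdgeSet) -> list[tuple[Item, Item, float]]:
    lrank = {it: r for r, it in enumerate(
        sorted({left for left, _, _ in edges.edges}))}
    rrank = {it: r for r, it in enumerate(
        sorted({right for _, right, _ in edges.edges}))}
    return sorted(edges.edges, key=lambda e: (-e[2], lrank[e[0]], rrank[e[1]]))


def greedy_maximal_matching(edges: WeightedEdgeSet) -> MatchingResult:
    """Heaviest-first maximal matching on the positive-weight subgraph.

    Scans edges by (weight desc, left asc, right asc) and takes an edge iff
    both endpoints are free.  The result is maximal among positive-weight
    edges and carries at least half the maximum matching weight.
    """
    used_l: set[Item] = set()
    used_r: set[Item] = set()
    pairs: list[tuple[Item, Item]] = []
    total = 0.0
    for left, right, w in _sorted_edges(edges):
        if w == 0.0:
            break  # sorted by weight: everything after is zero too
        if left not in used_l and right not in used_r:
            used_l.add(left)
            used_r.add(right)
            pairs.append((left, right))
            total += w
    return MatchingResult(tuple(pairs), total)


def optimal_matching(edges: WeightedEdgeSet) -> MatchingResult:
    """Maximum weighted matching via the assignment algorithm."""
    if not len(edges):
        return MatchingResult((), 0.0)
    lefts = sorted({left for left, _, _ in edges.edges})
    rights = sorted({right for _, right, _ in edges.edges})
    li = {it: i for i, it in enumerate(lefts)}
    ri = {it: i for i, it in enumerate(rights)}
    w = np.zeros((len(lefts), len(rights)))
    for left, right, s in edges.edges:
        w[li[left], ri[right]] = s
    rows, cols = linear_sum_assignment(w, maximize=True)
    pairs = tuple((lefts[r], rights[c]) for r, c in zip(rows, cols)
                  if w[r, c] > 0.0)
    total = float(w[rows, cols].sum())
    return MatchingResult(pairs, total)


def exhaustive_matching(edges: WeightedEdgeSet, limit: int = 10
                        ) -> MatchingResult:
    """Brute-force optimum over all matchings (test oracle, tiny inputs).

    Raises if either side has more than ``limit`` items.
    """
    lefts = sorted({left for left, _, _ in edges.edges})
    rights = sorted({right for _, right, _ in edges.edges})
    if len(lefts) > limit or len(rights) > limit:
        raise OntologyError(
            f"exhaustive matching guard exceeded ({len(lefts)}x{len(rights)} "
            f"items, limit {limit} per side)")
    adj: dict[Item, list[tuple[Item, float]]] = {left: [] for left in lefts}
    for left, right, w in edges.edges:
        adj[left].append((right, w))

    best_total = 0.0
    best_pairs: tuple[tuple[Item, Item], ...] = ()

    def recurse(i: int, used_r: set[Item], acc: float,
                pairs: list[tuple[Item, Item]]) -> None:
        nonlocal best_total, best_pairs
        if i == len(lefts):
            if acc > best_total:
                best_total, best_pairs = acc, tuple(pairs)
            return
        left = lefts[i]
        recurse(i + 1, used_r, acc, pairs)  # leave `left` unmatched
        for right, w in adj[left]:
            if w > 0.0 and right not in used_r:
                used_r.add(right)
                pairs.append((left, right))
                recurse(i + 1, used_r, acc + w, pairs)
                pairs.pop()
                used_r.discard(right)

    recurse(0, set(), 0.0, [])
    return MatchingResult(best_pairs, best_total)


MATCHERS = {
    "greedy": greedy_maximal_matching,
    "optimal": optimal_matching,
    "exhaustive": exhaustive_matching,
}
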