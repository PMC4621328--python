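"""Random benchmark instances: MST-shaped trees and uniform closeness.

Each random ontology is built by drawing a symmetric matrix of i.i.d.
uniform(0, 1) weights over ``n`` vertices, taking its minimum spanning tree,
rooting it at vertex 0 and orienting edges away from the root.  (With i.i.d.
uniform weights, minimum- and maximum-weight spanning trees are identically
distributed, so the choice of "minimum" cannot bias any result.)  Closeness
between two ontologies assigns an independent uniform(0, 1) score to every
cross pair of terms.

Everything is deterministic given the seed; no global randomness is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree

from .core import ClosenessMatrix, MatrixBank, OntologyError, OntologyTree, build_tree

__all__ = ["BenchmarkSpec", "Instance", "benchmark_suite", "random_closeness",
           "random_tree"]


def _term_ids(ontology_id: str, n: int) -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"{ontology_id}.t{i:0{width}d}" for i in range(n)]


def random_tree(n: int, seed, ontology_id: str = "T") -> OntologyTree:
    """Random ontology: minimum spanning tree of a random symmetric matrix,
    rooted at vertex 0 with edges oriented away from the root."""
    if n < 1:
        raise OntologyError(f"n must be >= 1, got {n}")
    ids = _term_ids(ontology_id, n)
    if n == 1:
        return build_tree([], ontology_id, root=ids[0])
    rng = np.random.default_rng(seed)
    w = rng.random((n, n))
    w = np.triu(w, 1)
    w = w + w.T  # symmetric, zero diagonal
    mst = minimum_spanning_tree(w).toarray()
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in zip(*np.nonzero(mst)):
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    edges: list[tuple[str, str]] = []
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                edges.append((ids[v], ids[u]))
                stack.append(v)
    return build_tree(edges, ontology_id)


def random_closeness(t_a: OntologyTree, t_b: OntologyTree, seed
                     ) -> ClosenessMatrix:
    """Independent uniform(0, 1) closeness for every cross pair of terms."""
    rng = np.random.default_rng(seed)
    arr = rng.random((t_a.n, t_b.n))
    return ClosenessMatrix.from_array(t_a.ontology_id, t_b.ontology_id,
                                      t_a.terms(), t_b.terms(), arr)


@dataclass(frozen=True)
class BenchmarkSpec:
    """Shape of a replicated multi-ontology benchmark."""

    k: int = 10
    n: int = 100
    replicates: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.k < 2 or self.n < 1 or self.replicates < 1:
            raise OntologyError(f"invalid benchmark spec {self}")


@dataclass(frozen=True)
class Instance:
    """One replicate: k trees plus all pairwise closeness matrices."""

    replicate: int
    trees: tuple[OntologyTree, ...]
    matrices: MatrixBank


def make_instance(k: int, n: int, seed: int, replicate: int = 0) -> Instance:
    """Build one instance; all sub-seeds derive deterministically from
    (seed, replicate)."""
    master = np.random.default_rng([int(seed), int(replicate)])
    trees = tuple(
        random_tree(n, int(master.integers(2**31)), ontology_id=f"O{i:02d}")
        for i in range(k))
    bank = MatrixBank()
    for i in range(k):
        for j in range(i + 1, k):
            bank.add(random_closeness(trees[i], trees[j],
                                      int(master.integers(2**31))))
    return Instance(replicate, trees, bank)


def benchmark_suite(spec: BenchmarkSpec) -> Iterator[Instance]:
    """Yield ``spec.replicates`` independent instances for the spec."""
    for r in range(spec.replicates):
        yield make_instance(spec.k, spec.n, spec.seed, replicate=r)
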