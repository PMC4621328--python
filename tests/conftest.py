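"""Shared fixtures: hand-checked tiny integration instances."""

import numpy as np
import pytest

from ontofuse import ClosenessMatrix, MatrixBank, build_tree
from ontofuse.synthetic import random_closeness, random_tree


@pytest.fixture
def e1():
    """Two 3-vertex stars with one cross matrix.

    Optimal integration merges all three pairs for cohesion 6; the greedy
    kernel's heaviest-first child matching takes (a1, b2) only, for 5.
    """
    t_a = build_tree([("a1", "a0"), ("a2", "a0")], "A")
    t_b = build_tree([("b1", "b0"), ("b2", "b0")], "B")
    m = ClosenessMatrix("A", "B", {("a0", "b0"): 1.0, ("a1", "b1"): 2.0,
                                   ("a2", "b2"): 3.0, ("a1", "b2"): 4.0})
    return t_a, t_b, m


@pytest.fixture
def e2():
    """Three single-vertex ontologies; full merge scores 0.9+0.2+0.5."""
    t1 = build_tree([], "T1", root="x")
    t2 = build_tree([], "T2", root="y")
    t3 = build_tree([], "T3", root="z")
    bank = MatrixBank([
        ClosenessMatrix("T1", "T2", {("x", "y"): 0.9}),
        ClosenessMatrix("T1", "T3", {("x", "z"): 0.2}),
        ClosenessMatrix("T2", "T3", {("y", "z"): 0.5}),
    ])
    return (t1, t2, t3), bank


def random_pair(seed: int, max_n: int = 7):
    """A random tree pair with dense uniform closeness, sizes 2..max_n."""
    rng = np.random.default_rng(seed)
    na = int(rng.integers(2, max_n + 1))
    nb = int(rng.integers(2, max_n + 1))
    t_a = random_tree(na, int(rng.integers(2**31)), "A")
    t_b = random_tree(nb, int(rng.integers(2**31)), "B")
    m = random_closeness(t_a, t_b, int(rng.integers(2**31)))
    return t_a, t_b, m
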