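"""Readers and writers for the on-disk formats.

Trees travel as 2-column child/parent TSV or as MRHIER-style path files
(one root-to-term path per line, a configurable delimiter between terms;
merging common prefixes from the root reconstructs the tree).  Closeness
matrices are sparse 3-column TSV triples.  Integrated ontologies are
written as one record per merged node (node id, parent id, members,
weight) plus an optional Graphviz DOT rendering whose node labels carry
the closeness weight and subtree cohesion.

Term identifiers are opaque strings; CUI-like or GO-like ids are equally
fine and never parsed semantically.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

from .core import ClosenessMatrix, OntologyError, OntologyTree, build_tree
from .pairwise import IntegratedOntology, MergedNode

__all__ = [
    "read_closeness_tsv", "read_merged_tsv", "read_mrhier_paths",
    "read_tree_tsv", "write_closeness_tsv", "write_dot", "write_merged_tsv",
    "write_tree_tsv",
]


def _rows(path) -> Iterable[tuple[int, list[str]]]:
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].lstrip().startswith("#"):
                continue
            yield lineno, [c.strip() for c in row]


def read_tree_tsv(path, ontology_id: str | None = None) -> OntologyTree:
    """Read a tree from 2-column child TAB parent lines (header optional)."""
    path = Path(path)
    edges: list[tuple[str, str]] = []
    root: str | None = None
    for lineno, row in _rows(path):
        if len(row) != 2:
            raise OntologyError(
                f"{path}:{lineno}: expected 2 columns, got {len(row)}")
        if lineno == 1 and row[0].lower() in {"child", "term"}:
            continue
        if not row[1]:  # empty parent declares the root
            root = row[0]
            continue
        edges.append((row[0], row[1]))
    if not edges and root is None:
        raise OntologyError(f"{path}: no edges found")
    return build_tree(edges, ontology_id or path.stem, root=root)


def write_tree_tsv(tree: OntologyTree, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow([tree.root, ""])
        for v in range(2, tree.n + 1):
            w.writerow([tree.ids[v], tree.ids[tree.parent[v]]])


def read_mrhier_paths(path, ontology_id: str | None = None,
                      delimiter: str = ".") -> OntologyTree:
    """Build a tree from root-to-term paths, merging common prefixes.

    Each line is a path from the root to a term, terms separated by
    ``delimiter`` (UMLS releases vary; the delimiter is configurable).
    A term appearing under two different parents is flagged as DAG input.
    """
    path = Path(path)
    edges: dict[str, str] = {}
    root: str | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            terms = [t.strip() for t in line.split(delimiter) if t.strip()]
            if not terms:
                continue
            if root is None:
                root = terms[0]
            elif terms[0] != root:
                raise OntologyError(
                    f"{path}:{lineno}: path starts at {terms[0]!r}, "
                    f"expected root {root!r}")
            for parent, child in zip(terms, terms[1:]):
                if edges.get(child, parent) != parent:
                    raise OntologyError(
                        f"{path}:{lineno}: term {child!r} has two parents "
                        f"({edges[child]!r}, {parent!r}); DAG input must be "
                        "pre-expanded")
                edges[child] = parent
    if root is None:
        raise OntologyError(f"{path}: no paths found")
    return build_tree([(c, p) for c, p in edges.items()],
                      ontology_id or path.stem, root=root)


def read_closeness_tsv(path, side_a: str | None = None,
                       side_b: str | None = None) -> ClosenessMatrix:
    """Read sparse (term_a, term_b, score) triples.

    Side names default to ``<stem>`` split on ``__`` when the file is named
    ``A__B.tsv``, else ``"A"``/``"B"``.
    """
    path = Path(path)
    if side_a is None or side_b is None:
        parts = path.stem.split("__")
        if len(parts) == 2:
            side_a, side_b = side_a or parts[0], side_b or parts[1]
        else:
            side_a, side_b = side_a or "A", side_b or "B"
    entries: dict[tuple[str, str], float] = {}
    for lineno, row in _rows(path):
        if len(row) != 3:
            raise OntologyError(
                f"{path}:{lineno}: expected 3 columns, got {len(row)}")
        try:
            score = float(row[2])
        except ValueError:
            if lineno == 1:
                continue  # header
            raise OntologyError(f"{path}:{lineno}: bad score {row[2]!r}")
        key = (row[0], row[1])
        if key in entries:
            raise OntologyError(f"{path}:{lineno}: duplicate pair {key}")
        if score < 0:
            raise OntologyError(
                f"{path}:{lineno}: negative closeness {score}")
        entries[key] = score
    return ClosenessMatrix(side_a, side_b, entries)


def write_closeness_tsv(m: ClosenessMatrix, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for a, b, s in sorted(m.items()):
            w.writerow([a, b, repr(s)])


# ---------------------------------------------------------------------------
# Integrated ontology serialisation
# ---------------------------------------------------------------------------

def write_merged_tsv(onto: IntegratedOntology, path) -> None:
    """One record per node: node_id, parent_node_id, members, weight.

    Members are ``ontology_id:term_id`` joined by commas; the root's parent
    field is empty.  Record order is node (breadth-compatible) order.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["node_id", "parent_node_id", "members", "weight"])
        for i, nd in enumerate(onto.nodes):
            members = ",".join(f"{o}:{t}" for o, t in nd.members)
            w.writerow([f"n{i}", "" if i == 0 else f"n{nd.parent}",
                        members, repr(nd.weight)])


def read_merged_tsv(path) -> IntegratedOntology:
    path = Path(path)
    nodes: list[MergedNode] = []
    ids: dict[str, int] = {}
    for lineno, row in _rows(path):
        if row[0] == "node_id":
            continue
        if len(row) != 4:
            raise OntologyError(
                f"{path}:{lineno}: expected 4 columns, got {len(row)}")
        nid, pid, members_s, weight_s = row
        members = tuple(
            tuple(part.split(":", 1)) for part in members_s.split(",")
            if part)
        if any(len(m) != 2 for m in members):
            raise OntologyError(f"{path}:{lineno}: malformed members "
                                f"{members_s!r}")
        parent = None if not pid else ids[pid]
        ids[nid] = len(nodes)
        nodes.append(MergedNode(members, parent, float(weight_s)))  # type: ignore[arg-type]
    if not nodes:
        raise OntologyError(f"{path}: empty merged-ontology file")
    onts = {o for nd in nodes for o, _ in nd.members}
    total = sum(nd.weight for nd in nodes)
    return IntegratedOntology(nodes, total, onts)


def write_dot(onto: IntegratedOntology, path) -> None:
    """Graphviz DOT rendering; labels show [closeness | subtree cohesion]."""
    # Subtree cohesion: node weight plus the weights of all descendants.
    subtree = [nd.weight for nd in onto.nodes]
    for i in range(len(onto.nodes) - 1, 0, -1):
        subtree[onto.nodes[i].parent] += subtree[i]  # type: ignore[index]
    with open(path, "w") as fh:
        fh.write("digraph integrated {\n  rankdir=TB;\n")
        for i, nd in enumerate(onto.nodes):
            label = "; ".join(f"{o}:{t}" for o, t in nd.members) or "(root)"
            fh.write(f'  n{i} [label="{label}\\n'
                     f'[{nd.weight:.4g} | {subtree[i]:.4g}]"];\n')
        for i, nd in enumerate(onto.nodes):
            if i:
                fh.write(f"  n{nd.parent} -> n{i};\n")
        fh.write("}\n")
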