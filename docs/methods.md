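# Methods

## Model and assumptions

An ontology is a rooted tree of terms connected by child→parent (is_a-like)
edges. DAG-shaped hierarchies must be pre-expanded by the caller, treating
duplicated concepts as independent terms; the tree builder rejects a term
with two parents. Closeness between terms of different ontologies is an
externally supplied, finite, non-negative score (`ClosenessMatrix`); absent
pairs score zero, and no upper bound is assumed (the synthetic benchmark
uses [0, 1]).

An integrated ontology is a tree of nodes, each node holding at most one
term per source ontology; every source term appears in exactly one node
(unmatched terms occupy singleton nodes of weight 0). A node's weight is
the summed closeness over its member pairs, the total cohesion is the sum
of node weights, and integration must preserve each source's
lowest-common-ancestor structure: for any two terms of one source, their
source LCA is a member of the LCA node of their merged images
(`validate_lca_preservation` checks all within-source pairs exhaustively, using
binary-lifting LCA queries on the merged tree).

Every tree exposes a virtual super-root (index 0) whose only child is the
real root and whose closeness to everything is 0. This lets root-vs-root
and whole-tree integration share one recurrence: the cohesion matrix entry
(0, 0) is the answer, and reconstruction starts from the merged virtual
roots.

## Pairwise integration

`build_cohesion_matrix` fills the (n+1) × (m+1) table in reverse
topological order (children carry larger breadth-first indices than
parents, so a simple descending index scan suffices). Entry (i, j) is the
maximum of:

* `M(i, j)` + weight of a matching of i's child forest against j's child
  forest, with already-computed entries as edge weights (merge the roots);
* `max_y entry(i, y)` over j's children (j's root stays out, above);
* `max_x entry(x, j)` over i's children (symmetric).

Each table entry is read at most once as a matching edge weight (when its
parents' entry is computed), so the amortised matching cost over the whole
table is O(n·m) edge visits; with heaviest-first maximal matching the whole
DP runs in O(n² log n).

Two matching kernels are interchangeable. `optimal` solves the assignment
problem (scipy's `linear_sum_assignment`) and makes the DP exact.
`greedy` scans edges by (weight desc, left index asc, right index asc) and
takes an edge iff both endpoints are free; it retains at least half the
maximum matching weight, and empirically the end-to-end cohesion stays well
above the ½ bound (worst observed ratio ≈ 0.85 over 200 random instances in
the acceptance run). Both kernels skip zero-weight edges: merging terms
with zero closeness adds nothing but constrains descendants. Note this
applies to the *matching* only — the DP itself may still merge a
zero-closeness term pair when entry > 0, i.e. when their descendants
benefit; that behaviour is deliberate and preserved.

`build_integrated_ontology` reconstructs the merged tree top-down from
entry (0, 0) with a queue of (i, j, parent-node) triples, instead of
storing the decisions (which would cost O(n³) memory). At each triple the
three candidates are recomputed with the same kernel and compared to the
stored entry by exact float equality — legitimate because identical
arithmetic is replayed on identical inputs; this is why kernel determinism
(fixed tie-breaks) is load-bearing, and why the reconstruction refuses to
run with a kernel different from the one that built the table. The case
preference order (merge > descend-into-B > descend-into-A) is arbitrary but
fixed; any order reproducing the entry is score-equivalent. Cross-checks
between *different* computations (reconstructed cohesion vs table entry,
DP vs oracles) use a 1e-9 absolute tolerance, since different summation
orders legitimately differ in the last bits.

## Heuristic integration

`heuristic_integrate` is a single top-down pass: walking T_A in BFS order,
each vertex may merge with an *allowable* candidate in T_B — a descendant
of its nearest merged ancestor's partner that no sibling branch has
claimed. Claiming is exclusive per top-level subtree of the partner's child
forest: once one child branch reaches into a subtree, no other branch may
use any of its vertices. This exclusivity is not optional bookkeeping; if
two incomparable branches of T_A merged into the same T_B subtree, the
shared B-side ancestor could not sit in any valid LCA node, breaking
preservation. Candidates are scored `M(a, b) / beta^rdepth(b)` where
`rdepth` is the candidate's depth below the shallowest allowable candidate;
`beta = 1` (default) disables depth weighting, large beta confines choices
to the shallowest candidates. Merges require strictly positive closeness —
a zero-closeness merge can only lose future opportunities here. Both
conventions (positive-closeness merges, rdepth measured within the current
candidate set) are this package's choices; they make the beta = 1 and
beta → ∞ limits behave as described and avoid meaningless merges.

## Multi-ontology integration

A merged unit is integrated further by treating its node tree as an
ontology whose "terms" are nodes, with closeness to an outside node given
by the sum over cross-ontology member pairs (`merge_closeness`). All three
strategies reduce to the pairwise machinery this way:

* **basic** folds units in input order;
* **greedy** maintains adjusted cohesion scores — the cross-pair weight
  increase of integrating two units divided by |X|·|Y| member ontologies,
  which removes the advantage big units have in raw scores — and always
  integrates the best active pair, rescoring only the new unit's edges;
* **fast** computes the pairwise cohesion graph once, then contracts the
  current maximum edge k−1 times, collapsing parallel edges to the maximum
  of the two stale weights. True weight increases only grow under
  contraction (verified empirically here: 0 violations in 200 randomized
  trials with the optimal kernel), so the stale maximum remains a valid
  lower bound and the final cohesion is at least the maximum-spanning-tree
  weight of the initial graph; with optimal pairwise matching it is at
  least 1/(k−1) of the optimum. With the greedy kernel the package still
  checks the MST bound at run time but does not claim the 1/(k−1)
  constant. When the maximum remaining edge weight is 0, contraction
  proceeds anyway (smallest-id pair first) so a single tree always results.

An empirical note this package's own benchmark computes (see
`scripts/acceptance.py` output): under the synthetic conditions below, the
mean cohesion ordering at k = 10 is Basic ≳ Fast > Greedy, with Basic ahead
of Fast by ~1–2 % at every size, while Basic is also the fastest and Greedy
by far the slowest. Keeping one side of every integration a fresh,
maximally flexible tree (Basic) appears to capture slightly more cross
closeness than contracting two already-rigid units (Fast). The proven
guarantees (MST lower bound, 1/(k−1) at small k) hold in every run; the
*ranking* between heuristic strategies carries no guarantee in either
direction and should be expected to depend on data.

## Synthetic benchmark

`random_tree(n, seed)` draws a symmetric matrix of i.i.d. uniform(0, 1)
weights, takes its minimum spanning tree, roots it at vertex 0 and orients
edges away from the root. With i.i.d. uniform weights, minimum- and
maximum-weight spanning trees are identically distributed, so the "minimum"
choice cannot bias results. `random_closeness` scores every cross pair
independently uniform(0, 1). All sub-seeds derive from a
(seed, replicate) seed sequence; there is no global randomness.

What this emulates: ontologies of realistic size with low-degree,
moderately deep tree shapes and dense, unstructured similarity. What it
does not emulate: power-law branching, sparse or block-structured closeness
matrices, and correlation between tree structure and closeness — all
present in real term-similarity data. Passing benchmarks here therefore
demonstrate algorithmic correctness and the proven bounds, not performance
rankings on any particular real ontology pair.

Problem sizes used by the default acceptance run (chosen to keep the full
suite in the low minutes on one CPU for this pure-Python implementation):
200 random pairs of 2–7 vertices for the oracle and ½-bound sweeps; 100
replicates of k = 3, n = 4 for the exhaustive multi-way comparisons;
contraction runs at (k = 4, n = 30) and (k = 10, n = 100) for the MST
bound; and a strategy benchmark at k = 10, n ∈ {60, 100, 140} with 10
replicates per size.

## Oracles

Two independent pairwise oracles guard the DP. The first recurses on the
root-merge cases with exhaustively enumerated forest matchings. The second
enumerates merge mappings directly, using the characterisation that a set
of merged pairs is realizable iff the induced partial injection preserves
ancestor order and incomparability in both directions and is closed under
LCA (if (a1, b1) and (a2, b2) merge, so do (lca(a1,a2), lca(b1,b2))). This
characterisation is derived here, not taken from elsewhere, and is
therefore cross-validated against the first oracle rather than trusted
alone. The multi-way oracle generalises the forest recursion: trees are
partitioned into merged subtrees holding at most one tree per source
forest (two trees of one forest in a single merged subtree always break
LCA preservation), and within a group every non-empty subset of roots may
form the top node. All oracles carry hard size guards (7 vertices per tree
pairwise; k ≤ 3, n ≤ 4 multi-way).

## Known limitations

* Inputs must be trees; DAG expansion is the caller's responsibility.
* Closeness matrices are inputs; computing them from corpora or knowledge
  graphs is out of scope.
* The cohesion matrix is dense (O(n·m) doubles), which bounds practical
  pairwise sizes to a few tens of thousands of terms in this
  implementation.
* The ½ bound is proven per matching; its end-to-end composition through
  the DP is checked empirically (never violated in any run) rather than
  proven level-by-level here.
* MRHIER-style path parsing accepts a configurable delimiter; real UMLS
  releases vary in delimiter and ordering, and only the path dialect is
  supported, not full RRF ingestion.
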