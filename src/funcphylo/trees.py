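"""Tree inference and comparison for genome term profiles.

Trees are :class:`dendropy.Tree` objects throughout; this module layers
on top of dendropy the operations the profile pipeline needs:

* ``neighbor_joining`` — Saitou–Nei agglomeration with the standard
  Q-criterion and Studier–Keppler branch-length updates.  On an additive
  distance matrix the generating topology and branch lengths are
  recovered exactly.  Ties in Q are broken toward the lexicographically
  smallest pair of cluster labels so results are deterministic.
* ``fitch_score`` / ``parsimony_search`` — small-parsimony scoring of a
  genome x term presence matrix (minimum number of 0<->1 changes) and a
  search for the minimum-score topology: exhaustive enumeration of all
  unrooted binary topologies up to a size limit, stepwise addition with
  random addition orders plus nearest-neighbor-interchange refinement
  beyond it.
* split utilities — bipartition extraction, Robinson–Foulds distance,
  strict majority-rule consensus with per-split frequencies, rooting at
  an outgroup, pruning, and contraction of named monophyletic groups.

All splits are represented as frozensets of leaf labels, normalised to
the side *not* containing the lexicographically smallest leaf, which
makes comparisons independent of dendropy taxon namespaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .profiles import BinaryMatrix, DistanceMatrix

__all__ = [
    "parse_newick",
    "write_newick",
    "leaf_labels",
    "splits",
    "rf_distance",
    "neighbor_joining",
    "fitch_score",
    "parsimony_search",
    "ParsimonyResult",
    "root_at_outgroup",
    "split_frequencies",
    "majority_rule_consensus",
    "annotate_supports",
    "restrict_to_taxa",
    "contract_groups",
    "canonical_newick",
]

Tree = dendropy.Tree


# ---------------------------------------------------------------------------
# newick io


def parse_newick(text: str) -> Tree:
    """Parse a Newick string; internal node labels are kept as labels
    (typically supports).  Raises ``ValueError`` on malformed input or
    duplicate leaf names."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"invalid newick: {exc}") from exc
    return tree


def write_newick(tree: Tree) -> str:
    """Serialise with branch lengths and internal labels, no rooting tag."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def leaf_labels(tree: Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def _clade_map(tree: Tree) -> dict:
    """node -> frozenset of leaf labels below it (current orientation)."""
    clades: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            clades[node] = frozenset({node.taxon.label})
        else:
            acc: set[str] = set()
            for ch in node.child_nodes():
                acc |= clades[ch]
            clades[node] = frozenset(acc)
    return clades


def _normalise(side: frozenset[str], leaves: frozenset[str], anchor: str):
    if anchor in side:
        side = leaves - side
    if 2 <= len(side) <= len(leaves) - 2:
        return side
    return None


def splits(tree: Tree) -> frozenset[frozenset[str]]:
    """Non-trivial bipartitions as anchor-normalised leaf-label sets."""
    leaves = leaf_labels(tree)
    if len(leaves) < 4:
        return frozenset()
    anchor = min(leaves)
    out: set[frozenset[str]] = set()
    clades = _clade_map(tree)
    for node, clade in clades.items():
        if node is tree.seed_node:
            continue
        side = _normalise(clade, leaves, anchor)
        if side is not None:
            out.add(side)
    return frozenset(out)


def rf_distance(tree_a: Tree, tree_b: Tree) -> int:
    """Robinson–Foulds distance: splits present in exactly one tree."""
    la, lb = leaf_labels(tree_a), leaf_labels(tree_b)
    if la != lb:
        raise ValueError(
            f"leaf sets differ: only-in-a={sorted(la - lb)}, "
            f"only-in-b={sorted(lb - la)}"
        )
    return len(splits(tree_a) ^ splits(tree_b))


def canonical_newick(tree: Tree) -> str:
    """Deterministic topology-only Newick (children sorted by smallest
    descendant leaf label); used for reproducible tie-breaking."""

    def render(node) -> tuple[str, str]:
        if node.is_leaf():
            return node.taxon.label, node.taxon.label
        parts = sorted(render(ch) for ch in node.child_nodes())
        key = parts[0][0]
        return key, "(" + ",".join(p[1] for p in parts) + ")"

    return render(tree.seed_node)[1] + ";"


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(
    dm: DistanceMatrix, clamp_negative: bool = False
) -> Tree:
    """Saitou–Nei neighbor joining on a symmetric distance matrix.

    Returns an unrooted tree with branch lengths.  Negative branch
    lengths (possible for non-additive input) are retained unless
    ``clamp_negative`` is set.  Q-criterion ties join the pair whose
    (sorted) cluster label pair is lexicographically smallest, where a
    cluster's label is the smallest leaf label it contains.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    keys: list[str] = []  # smallest leaf label per active cluster
    for lab in dm.labels:
        taxon = tns.new_taxon(label=lab)
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)
        keys.append(lab)
    D = dm.values.astype(float).copy()

    def finish(tree_root: dendropy.Node) -> Tree:
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.seed_node = tree_root
        tree.is_rooted = False
        if clamp_negative:
            for edge in tree.preorder_edge_iter():
                if edge.length is not None and edge.length < 0:
                    edge.length = 0.0
        return tree

    if n == 2:
        root = dendropy.Node()
        for node in nodes:
            node.edge.length = D[0, 1] / 2.0
            root.add_child(node)
        return finish(root)

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((keys[active[i]], keys[active[j]]))), i, j)
            for i, j in ties
            if i < j
        )
        _, ai, aj = best
        i_glob, j_glob = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        nodes[i_glob].edge.length = li
        nodes[j_glob].edge.length = lj
        parent.add_child(nodes[i_glob])
        parent.add_child(nodes[j_glob])
        # Studier–Keppler distance update, stored in slot i_glob
        for k in active:
            if k in (i_glob, j_glob):
                continue
            dnew = 0.5 * (D[i_glob, k] + D[j_glob, k] - dij)
            D[i_glob, k] = D[k, i_glob] = dnew
        nodes[i_glob] = parent
        keys[i_glob] = min(keys[i_glob], keys[j_glob])
        active.remove(j_glob)

    # final three clusters join at a central node (closed form)
    a, b, c = active
    root = dendropy.Node()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].edge.length = length
        root.add_child(nodes[idx])
    return finish(root)


def path_distance_matrix(tree: Tree) -> tuple[DistanceMatrix, float]:
    """Patristic (path-length) distances between all leaf pairs,
    rescaled by the maximum so they fit the :class:`DistanceMatrix`
    [0, 1] contract.  Returns (matrix, scale); multiply by ``scale`` to
    recover the raw distances.  On such an additive matrix NJ recovers
    the generating topology and (scaled) branch lengths exactly."""
    labels = sorted(leaf_labels(tree))
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(
                taxa[labels[i]], taxa[labels[j]]
            )
    scale = float(D.max()) if D.max() > 0 else 1.0
    return DistanceMatrix(labels=tuple(labels), values=D / scale), scale


# ---------------------------------------------------------------------------
# parsimony: adjacency-map machinery

_PRESENT = np.uint8(2)  # state set {1}
_ABSENT = np.uint8(1)  # state set {0}


def _compress_columns(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical columns into (patterns, weights); constant
    columns are dropped (they can never require a change)."""
    nonconst = values[:, values.min(axis=0) != values.max(axis=0)]
    if nonconst.shape[1] == 0:
        return np.zeros((values.shape[0], 0), dtype=np.uint8), np.zeros(0, int)
    patterns, counts = np.unique(nonconst, axis=1, return_counts=True)
    return patterns.astype(np.uint8), counts


def _leaf_states(patterns: np.ndarray) -> list[np.ndarray]:
    return [
        np.where(row == 1, _PRESENT, _ABSENT).astype(np.uint8)
        for row in patterns
    ]


def _score_adjacency(
    adj: Mapping[int, list[int]],
    leaf_states: Sequence[np.ndarray],
    weights: np.ndarray,
) -> int:
    """Fitch bottom-up pass, rooted on the edge of leaf 0.

    Exact for binary trees; for polytomies the children are folded
    sequentially, which yields an upper bound.
    """
    if weights.size == 0:
        return 0
    ncols = weights.shape[0]
    changes = np.zeros(ncols, dtype=np.int64)
    # orient from the smallest leaf's neighbor; that leaf joins last
    # via a virtual root (keeps every internal node binary)
    leaf0 = min(k for k in adj if len(adj[k]) == 1)
    start = adj[leaf0][0]
    parent = {start: leaf0}
    order = [start]
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v != parent[u]:
                parent[v] = u
                order.append(v)
                stack.append(v)
    state: dict[int, np.ndarray] = {}
    for u in reversed(order):
        kids = [v for v in adj[u] if parent.get(v) == u]
        if not kids:
            state[u] = leaf_states[u]
            continue
        acc = state[kids[0]]
        for v in kids[1:]:
            inter = acc & state[v]
            empty = inter == 0
            acc = np.where(empty, acc | state[v], inter)
            changes += empty
        state[u] = acc
    # virtual root joining the excluded leaf with the rest of the tree
    inter = state[start] & leaf_states[leaf0]
    changes += inter == 0
    return int((changes * weights).sum())


def _insert_leaf(adj: dict[int, list[int]], leaf: int, internal: int,
                 u: int, v: int) -> None:
    adj[u][adj[u].index(v)] = internal
    adj[v][adj[v].index(u)] = internal
    adj[internal] = [u, v, leaf]
    adj[leaf] = [internal]


def _remove_leaf(adj: dict[int, list[int]], leaf: int, internal: int,
                 u: int, v: int) -> None:
    del adj[leaf]
    del adj[internal]
    adj[u][adj[u].index(internal)] = v
    adj[v][adj[v].index(internal)] = u


def _edges(adj: Mapping[int, list[int]]) -> list[tuple[int, int]]:
    return sorted(
        (u, v) for u in adj for v in adj[u] if u < v
    )


def _adjacency_splits(
    adj: Mapping[int, list[int]], labels: Sequence[str]
) -> tuple[tuple[str, ...], ...]:
    """Canonical sorted tuple of non-trivial splits (tie-break key)."""
    n = len(labels)
    leaves = frozenset(labels)
    anchor = min(labels)
    start = adj[0][0]
    parent: dict[int, int | None] = {start: 0}
    order = [start]
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v != parent[u]:
                parent[v] = u
                order.append(v)
                stack.append(v)
    below: dict[int, frozenset[str]] = {}
    sides = set()
    for u in reversed(order):
        kids = [v for v in adj[u] if parent.get(v) == u]
        if not kids:
            below[u] = frozenset({labels[u]})
        else:
            below[u] = frozenset().union(*(below[v] for v in kids))
        side = _normalise(below[u], leaves, anchor)
        if side is not None:
            sides.add(side)
    return tuple(sorted(tuple(sorted(s)) for s in sides))


def _adjacency_to_tree(
    adj: Mapping[int, list[int]], labels: Sequence[str]
) -> Tree:
    tns = dendropy.TaxonNamespace()
    taxa = {i: tns.new_taxon(label=lab) for i, lab in enumerate(labels)}
    n = len(labels)
    if n == 2:
        root = dendropy.Node()
        for i in range(2):
            root.add_child(dendropy.Node(taxon=taxa[i]))
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.seed_node = root
        tree.is_rooted = False
        return tree
    seed_id = adj[0][0]  # internal neighbor of leaf 0
    node_of: dict[int, dendropy.Node] = {}

    def build(u: int, par: int | None) -> dendropy.Node:
        node = dendropy.Node(taxon=taxa.get(u))
        node_of[u] = node
        for v in adj[u]:
            if v != par:
                node.add_child(build(v, u))
        return node

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = build(seed_id, None)
    tree.is_rooted = False
    return tree


def _tree_to_adjacency(
    tree: Tree, labels: Sequence[str]
) -> dict[int, list[int]]:
    index = {lab: i for i, lab in enumerate(labels)}
    adj: dict[int, list[int]] = {}
    next_internal = len(labels)
    ids: dict = {}

    def node_id(node) -> int:
        nonlocal next_internal
        if node not in ids:
            if node.is_leaf():
                ids[node] = index[node.taxon.label]
            else:
                ids[node] = next_internal
                next_internal += 1
        return ids[node]

    for node in tree.preorder_node_iter():
        u = node_id(node)
        adj.setdefault(u, [])
        for ch in node.child_nodes():
            v = node_id(ch)
            adj.setdefault(v, [])
            adj[u].append(v)
            adj[v].append(u)
    return adj


def fitch_score(tree: Tree, matrix: BinaryMatrix) -> int:
    """Minimum number of 0<->1 changes of the matrix on the tree,
    summed over columns (Fitch small parsimony).  The tree's leaves
    must coincide with the matrix rows."""
    tree_leaves = leaf_labels(tree)
    rows = frozenset(matrix.row_labels)
    if tree_leaves != rows:
        raise ValueError(
            f"tree leaves and matrix rows differ: "
            f"only-in-tree={sorted(tree_leaves - rows)}, "
            f"only-in-matrix={sorted(rows - tree_leaves)}"
        )
    labels = sorted(matrix.row_labels)
    order = [matrix.row_labels.index(lab) for lab in labels]
    patterns, weights = _compress_columns(matrix.values[order])
    adj = _tree_to_adjacency(tree, labels)
    return _score_adjacency(adj, _leaf_states(patterns), weights)


def _enumerate_topologies(n: int):
    """Yield (mutable, reused) adjacency maps of every unrooted binary
    topology on leaves 0..n-1; (2n-5)!! of them."""
    adj: dict[int, list[int]] = {n: [0, 1, 2]}
    for i in range(3):
        adj[i] = [n]

    def rec(k: int, next_internal: int):
        if k == n:
            yield adj
            return
        for u, v in _edges(adj):
            _insert_leaf(adj, k, next_internal, u, v)
            yield from rec(k + 1, next_internal + 1)
            _remove_leaf(adj, k, next_internal, u, v)

    yield from rec(3, n + 1)


@dataclass
class ParsimonyResult:
    tree: Tree
    score: int
    method: str
    notes: list[str] = field(default_factory=list)


def _caterpillar_adjacency(n: int) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {n: [0, 1]}
    adj[0], adj[1] = [n], [n]
    prev = n
    for k in range(2, n - 1):
        internal = n + k - 1
        adj[prev].append(internal)
        adj[internal] = [prev, k]
        adj[k] = [internal]
        prev = internal
    adj[prev].append(n - 1)
    adj[n - 1] = [prev]
    return adj


def _nni_neighbors(adj: dict[int, list[int]]):
    """Yield (apply, undo) closures for each NNI move, deterministically."""
    for u, v in _edges(adj):
        if len(adj[u]) != 3 or len(adj[v]) != 3:
            continue
        b = [x for x in adj[u] if x != v][1]
        cs = [x for x in adj[v] if x != u]
        for c in cs:
            def apply(u=u, v=v, b=b, c=c):
                adj[u][adj[u].index(b)] = c
                adj[v][adj[v].index(c)] = b
                adj[b][adj[b].index(u)] = v
                adj[c][adj[c].index(v)] = u

            def undo(u=u, v=v, b=b, c=c):
                adj[u][adj[u].index(c)] = b
                adj[v][adj[v].index(b)] = c
                adj[b][adj[b].index(v)] = u
                adj[c][adj[c].index(u)] = v

            yield apply, undo


def parsimony_search(
    matrix: BinaryMatrix,
    exhaustive_limit: int = 9,
    n_addition_orders: int = 10,
    seed: int = 0,
) -> ParsimonyResult:
    """Search for a minimum-change topology for a binary matrix.

    Up to ``exhaustive_limit`` taxa every unrooted binary topology is
    enumerated and the global optimum returned; beyond it, stepwise
    addition under ``n_addition_orders`` random leaf orders followed by
    NNI hill-climbing is used.  Equal-score ties are broken by the
    canonical split representation, so the result is deterministic for
    a given seed.
    """
    n = len(matrix.row_labels)
    if n < 3:
        raise ValueError("parsimony search needs at least 3 taxa")
    labels = sorted(matrix.row_labels)
    order = [matrix.row_labels.index(lab) for lab in labels]
    patterns, weights = _compress_columns(matrix.values[order])
    notes: list[str] = []
    if weights.size == 0:
        notes.append(
            "matrix has no variable columns; topology is arbitrary "
            "(canonical caterpillar returned)"
        )
        warnings.warn(notes[-1], stacklevel=2)
        adj = _caterpillar_adjacency(n)
        return ParsimonyResult(
            tree=_adjacency_to_tree(adj, labels), score=0,
            method="degenerate", notes=notes,
        )
    states = _leaf_states(patterns)

    best_score = None
    best_key = None
    best_adj = None

    def consider(adj: Mapping[int, list[int]], score: int) -> None:
        nonlocal best_score, best_key, best_adj
        if best_score is None or score < best_score:
            best_score = score
            best_key = _adjacency_splits(adj, labels)
            best_adj = {k: list(v) for k, v in adj.items()}
        elif score == best_score:
            key = _adjacency_splits(adj, labels)
            if key < best_key:
                best_key = key
                best_adj = {k: list(v) for k, v in adj.items()}

    if n <= exhaustive_limit:
        for adj in _enumerate_topologies(n):
            consider(adj, _score_adjacency(adj, states, weights))
        method = "exhaustive"
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_addition_orders):
            perm = list(rng.permutation(n))
            adj = _stepwise_addition(perm, states, weights, n)
            score = _score_adjacency(adj, states, weights)
            score = _nni_refine(adj, states, weights, score)
            consider(adj, score)
        method = "stepwise+nni"
    return ParsimonyResult(
        tree=_adjacency_to_tree(best_adj, labels),
        score=best_score,
        method=method,
        notes=notes,
    )


def _stepwise_addition(
    perm: list[int],
    states: Sequence[np.ndarray],
    weights: np.ndarray,
    n: int,
) -> dict[int, list[int]]:
    first = perm[:3]
    adj: dict[int, list[int]] = {n: list(first)}
    for i in first:
        adj[i] = [n]
    next_internal = n + 1
    for leaf in perm[3:]:
        best = None
        for u, v in _edges(adj):
            _insert_leaf(adj, leaf, next_internal, u, v)
            s = _score_adjacency(adj, states, weights)
            _remove_leaf(adj, leaf, next_internal, u, v)
            if best is None or s < best[0]:
                best = (s, u, v)
        _, u, v = best
        _insert_leaf(adj, leaf, next_internal, u, v)
        next_internal += 1
    return adj


def _nni_refine(
    adj: dict[int, list[int]],
    states: Sequence[np.ndarray],
    weights: np.ndarray,
    score: int,
) -> int:
    improved = True
    while improved:
        improved = False
        for apply, undo in _nni_neighbors(adj):
            apply()
            s = _score_adjacency(adj, states, weights)
            if s < score:
                score = s
                improved = True
                break
            undo()
    return score


# ---------------------------------------------------------------------------
# rooting, consensus, pruning, contraction


def root_at_outgroup(tree: Tree, outgroup: str) -> Tree:
    """Root on the outgroup's pendant edge (midpoint when lengths exist)."""
    rooted = tree.clone(depth=1)
    leaf = rooted.find_node_with_taxon_label(outgroup)
    if leaf is None:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
    length = leaf.edge.length
    if length is None:
        rooted.reroot_at_edge(leaf.edge, update_bipartitions=False)
    else:
        rooted.reroot_at_edge(
            leaf.edge, length1=length / 2.0, length2=length / 2.0,
            update_bipartitions=False,
        )
    rooted.is_rooted = True
    return rooted


def split_frequencies(trees: Sequence[Tree]) -> dict[frozenset[str], float]:
    """Percentage of trees containing each observed non-trivial split."""
    if not trees:
        raise ValueError("need at least one tree")
    leaves = leaf_labels(trees[0])
    counts: dict[frozenset[str], int] = {}
    for tree in trees:
        if leaf_labels(tree) != leaves:
            raise ValueError("all trees must share the same leaf set")
        for side in splits(tree):
            counts[side] = counts.get(side, 0) + 1
    return {s: 100.0 * c / len(trees) for s, c in counts.items()}


def majority_rule_consensus(trees: Sequence[Tree]) -> Tree:
    """Strict majority-rule consensus: splits in more than half of the
    trees, each labelled with its percentage (one decimal).  Splits at
    exactly 50% are excluded."""
    freqs = split_frequencies(trees)
    leaves = sorted(leaf_labels(trees[0]))
    anchor = leaves[0]
    kept = {s: f for s, f in freqs.items() if f > 50.0}

    tns = dendropy.TaxonNamespace()
    taxa = {lab: tns.new_taxon(label=lab) for lab in leaves}
    top = frozenset(leaves[1:])
    clades = sorted(kept, key=len)  # parents appear after children
    nodes: dict[frozenset[str], dendropy.Node] = {top: dendropy.Node()}
    for clade in clades:
        node = dendropy.Node()
        node.label = f"{kept[clade]:.1f}"
        nodes[clade] = node
    # attach each clade/leaf to its smallest strict superset
    def parent_of(target: frozenset[str]) -> dendropy.Node:
        best = top
        for clade in clades:
            if target < clade and len(clade) < len(best):
                best = clade
        return nodes[best]

    for clade in sorted(kept, key=len, reverse=True):
        parent_of(clade).add_child(nodes[clade])
    for lab in leaves[1:]:
        parent_of(frozenset({lab})).add_child(
            dendropy.Node(taxon=taxa[lab])
        )
    root = nodes[top]
    root.add_child(dendropy.Node(taxon=taxa[anchor]))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def annotate_supports(
    tree: Tree, frequencies: Mapping[frozenset[str], float]
) -> Tree:
    """Label each internal node of a copy of ``tree`` with the replicate
    frequency of its split (0 when never observed)."""
    annotated = tree.clone(depth=1)
    leaves = leaf_labels(annotated)
    anchor = min(leaves)
    clades = _clade_map(annotated)
    for node, clade in clades.items():
        if node.is_leaf() or node is annotated.seed_node:
            continue
        side = _normalise(clade, leaves, anchor)
        if side is not None:
            node.label = f"{frequencies.get(side, 0.0):.1f}"
    return annotated


def restrict_to_taxa(tree: Tree, taxa: Iterable[str]) -> Tree:
    """Prune to the given taxa, suppressing degree-2 nodes."""
    taxa = set(taxa)
    leaves = leaf_labels(tree)
    missing = taxa - leaves
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)}")
    pruned = tree.extract_tree_with_taxa_labels(taxa)
    pruned.is_rooted = tree.is_rooted
    return pruned


def contract_groups(
    tree: Tree, groups: Mapping[str, Iterable[str]]
) -> Tree:
    """Replace each named (unrooted-)monophyletic group of leaves by a
    single leaf bearing the group name.  A group that is not
    monophyletic raises ``ValueError`` naming it."""
    work = tree.clone(depth=1)
    leaves = leaf_labels(work)
    groupsets = {name: frozenset(members) for name, members in groups.items()}
    for name, members in groupsets.items():
        extra = members - leaves
        if extra:
            raise ValueError(f"group {name!r}: members not in tree: {sorted(extra)}")
    groupsets = {n: m for n, m in groupsets.items() if len(m & leaves) >= 1}
    outside = sorted(leaves - frozenset().union(*groupsets.values())) \
        if groupsets else sorted(leaves)
    if groupsets and not outside:
        raise ValueError("groups cover every leaf; nothing to anchor on")
    if groupsets:
        # orient away from an outside leaf so each group, if monophyletic,
        # appears as a clade of the traversal
        anchor_leaf = work.find_node_with_taxon_label(outside[0])
        work.reroot_at_edge(anchor_leaf.edge, update_bipartitions=False)
        clades = _clade_map(work)
        by_clade = {clade: node for node, clade in clades.items()}
        for name in sorted(groupsets):
            members = groupsets[name]
            if len(members) == 1:
                node = work.find_node_with_taxon_label(next(iter(members)))
                node.taxon = work.taxon_namespace.new_taxon(label=name)
                continue
            node = by_clade.get(members)
            if node is None:
                raise ValueError(f"group {name!r} is not monophyletic")
            node.set_child_nodes([])
            node.taxon = work.taxon_namespace.new_taxon(label=name)
            node.label = None
    work.suppress_unifurcations()
    work.is_rooted = tree.is_rooted
    if not work.is_rooted and len(work.seed_node.child_nodes()) == 2:
        if not all(ch.is_leaf() for ch in work.seed_node.child_nodes()):
            work.collapse_basal_bifurcation()
    return work
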