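"""Neighbor-joining trees, nonparametric bootstrap, and monophyly checks.

This is the desk-scale distance-tree stage: neighbor-joining on uncorrected
p-distance matrices with column-resampling bootstrap supports.  Heavier
likelihood and parsimony searches belong to dedicated external tools; the
package exports PHYLIP alignments and distance matrices for them instead.

Determinism: ties in the NJ Q-criterion are broken by the lexicographically
smallest pair of cluster ids (a cluster is identified by its smallest leaf
label), and all bootstrap randomness flows from a single integer seed.
"""

from __future__ import annotations

import warnings
from typing import Callable, Iterable

import dendropy
import numpy as np

from .distances import DistanceMatrix, UndefinedDistanceError, p_distance_matrix
from .io import AlignedSeqSet

__all__ = [
    "nj_tree",
    "bootstrap_supports",
    "is_monophyletic",
    "split_set",
    "tree_distance_matrix",
]


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining (Q-criterion agglomeration) on a distance matrix.

    Returns an unrooted dendropy tree with non-negative branch lengths;
    a negative limb estimate is clamped to zero and the deficit moved to its
    sibling edge so the joined pair's path length is preserved.
    """
    n0 = len(dm)
    if n0 < 3:
        raise ValueError("neighbor-joining needs at least 3 sequences")
    d = np.array(dm.d, dtype=float)
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")

    tns = dendropy.TaxonNamespace(dm.ids)
    nodes: list[dendropy.Node] = []
    for sid in dm.ids:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(sid)
        nodes.append(node)
    # cluster tie-break key: smallest leaf label in the cluster
    keys: list[str] = list(dm.ids)
    active = list(range(n0))

    def join(i: int, j: int, li: float, lj: float) -> int:
        """Create the parent of active clusters i, j; returns its index in `nodes`."""
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        return len(nodes) - 1

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best: tuple[str, str] | None = None
        bi = bj = -1
        for a, b in np.argwhere(q <= qmin + 1e-12):
            if a >= b:
                continue
            pair = tuple(sorted((keys[active[a]], keys[active[b]])))
            if best is None or pair < best:
                best, bi, bj = pair, int(a), int(b)
        i, j = active[bi], active[bj]
        dij = sub[bi, bj]
        li = 0.5 * dij + (r[bi] - r[bj]) / (2.0 * (m - 2))
        lj = dij - li
        new = join(i, j, li, lj)
        # distances from the new node to the remaining clusters
        new_row = np.zeros(len(nodes))
        for b in range(m):
            k = active[b]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[new, : new + 1] = np.append(new_row[:new], 0.0)
        d[: new + 1, new] = d[new, : new + 1]
        active = [k for k in active if k not in (i, j)] + [new]

    # final three clusters join at the unrooted central node
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    center = dendropy.Node()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[k])
        nodes[k].edge.length = max(lk, 0.0)

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    # a zero-length internal edge carries no grouping signal: leave the node
    # unresolved rather than reporting an arbitrary tie-break as structure
    for node in list(tree.preorder_internal_node_iter()):
        if node is not tree.seed_node and (node.edge.length or 0.0) <= 0.0:
            node.edge.collapse()
    return tree


def _leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def split_set(tree: dendropy.Tree, nontrivial_only: bool = True) -> set[frozenset[str]]:
    """Canonical splits of an unrooted tree as leaf-label sets.

    Each edge bipartitions the leaves; the side *not* containing the
    lexicographically smallest leaf label is the canonical representative.
    Trivial splits (a single leaf) are dropped unless requested.
    """
    all_leaves = _leaf_labels(tree)
    if not all_leaves:
        return set()
    anchor = min(all_leaves)
    n = len(all_leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        side = below if anchor not in below else all_leaves - below
        if nontrivial_only and not (2 <= len(side) <= n - 2):
            continue
        if 1 <= len(side) <= n - 1:
            splits.add(side)
    return splits


def is_monophyletic(tree: dendropy.Tree, leaf_set: Iterable[str]) -> bool:
    """True iff some edge bipartitions the leaves into exactly (leaf_set, rest)."""
    target = frozenset(leaf_set)
    if not target:
        raise ValueError("leaf_set is empty")
    all_leaves = _leaf_labels(tree)
    unknown = target - all_leaves
    if unknown:
        raise ValueError(f"unknown leaf ids: {sorted(unknown)}")
    if target == all_leaves or len(target) == 1:
        return True
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if below == target or all_leaves - below == target:
            return True
    return False


def tree_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Patristic (path-length) distances between all leaf pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    n = len(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        ta = tree.taxon_namespace.get_taxon(a)
        for j in range(i + 1, n):
            tb = tree.taxon_namespace.get_taxon(labels[j])
            d[i, j] = d[j, i] = pdm.patristic_distance(ta, tb)
    return DistanceMatrix(ids=labels, d=d, m=np.ones((n, n), dtype=np.int64))


def bootstrap_supports(
    aln: AlignedSeqSet,
    tree_builder: Callable[[DistanceMatrix], dendropy.Tree] | None = None,
    reps: int = 100,
    seed: int | None = None,
) -> dendropy.Tree:
    """Point NJ tree with column-resampling bootstrap supports.

    Columns of the (already masked) alignment are resampled with replacement
    ``reps`` times; each internal split of the point tree is labelled with
    the integer percentage of replicate trees containing it.  Replicates in
    which some pair loses all comparable sites are discarded with a warning;
    more than 10% discarded aborts.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    builder = tree_builder or nj_tree
    point_tree = builder(p_distance_matrix(aln))

    rng = np.random.default_rng(seed)
    arr = np.array([list(row) for row in aln.rows])
    counts: dict[frozenset[str], int] = {s: 0 for s in split_set(point_tree)}
    discarded = 0
    valid = 0
    for _ in range(reps):
        cols = rng.integers(0, aln.length, size=aln.length)
        res_rows = ["".join(r) for r in arr[:, cols]]
        res = AlignedSeqSet(ids=list(aln.ids), rows=res_rows)
        try:
            rep_tree = builder(p_distance_matrix(res))
        except UndefinedDistanceError:
            discarded += 1
            warnings.warn("bootstrap replicate discarded: undefined pair distance")
            continue
        valid += 1
        for s in split_set(rep_tree):
            if s in counts:
                counts[s] += 1
    if discarded > 0.1 * reps:
        raise RuntimeError(
            f"{discarded}/{reps} bootstrap replicates discarded (>10%)"
        )

    all_leaves = _leaf_labels(point_tree)
    anchor = min(all_leaves)
    n = len(all_leaves)
    for node in point_tree.preorder_node_iter():
        if node is point_tree.seed_node or node.is_leaf():
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        side = below if anchor not in below else all_leaves - below
        if 2 <= len(side) <= n - 2 and valid > 0:
            node.label = str(int(round(100.0 * counts[side] / valid)))
    return point_tree


def split_support(tree: dendropy.Tree, leaf_set: Iterable[str]) -> int | None:
    """Bootstrap support (integer percent) recorded for a leaf set's split, if present."""
    target = frozenset(leaf_set)
    all_leaves = _leaf_labels(tree)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if below == target or all_leaves - below == target:
            return int(node.label) if node.label is not None else None
    return None
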