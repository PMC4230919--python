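"""Neighbor-joining, bootstrap supports, and monophyly checks.

NJ correctness is checked two independent ways: exact recovery of random
additive matrices built from known trees, and split-set agreement with
scikit-bio's neighbor-joining on the same input.
"""

import numpy as np
import pytest

from oophila.distances import DistanceMatrix, p_distance_matrix
from oophila.io import AlignedSeqSet
from oophila.tree import (
    bootstrap_supports,
    is_monophyletic,
    nj_tree,
    split_set,
    split_support,
    tree_distance_matrix,
)


def random_additive_matrix(n_leaves: int, rng):
    """Random binary tree by agglomeration; returns (ids, additive D, true split set).

    Distances are accumulated directly from the joins, independently of any
    tree data structure, so the matrix is additive by construction.
    """
    ids = [f"t{i:02d}" for i in range(n_leaves)]
    D = np.zeros((n_leaves, n_leaves))
    clusters = [({i}, {i: 0.0}) for i in range(n_leaves)]
    splits = []
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        la, lb = rng.uniform(0.05, 0.5, size=2)
        (sa, da), (sb, db) = clusters[i], clusters[j]
        for x, dx in da.items():
            for y, dy in db.items():
                D[x, y] = D[y, x] = dx + la + dy + lb
        merged_set = sa | sb
        merged_depth = {x: d + la for x, d in da.items()}
        merged_depth.update({y: d + lb for y, d in db.items()})
        if 2 <= len(merged_set) <= n_leaves - 2:
            splits.append(frozenset(ids[k] for k in merged_set))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((merged_set, merged_depth))
    # canonical split representation: the side not containing the smallest id
    anchor = min(ids)
    canon = {
        s if anchor not in s else frozenset(ids) - s
        for s in splits
        if 2 <= len(s) <= n_leaves - 2
    }
    return ids, D, canon


class TestNeighborJoining:
    def test_three_leaves_solve_three_point_formulas(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.4], [0.5, 0.4, 0.0]])
        tree = nj_tree(DistanceMatrix(ids=["a", "b", "c"], d=d, m=np.ones((3, 3), int)))
        lengths = {
            n.taxon.label: n.edge.length for n in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx(0.2)
        assert lengths["b"] == pytest.approx(0.1)
        assert lengths["c"] == pytest.approx(0.3)

    def test_four_leaf_additive_matrix_recovered_exactly(self):
        # hand-drawn tree: ((a:0.1,b:0.2):0.05,(c:0.15,d:0.25))
        d = np.array(
            [
                [0.0, 0.3, 0.3, 0.4],
                [0.3, 0.0, 0.4, 0.5],
                [0.3, 0.4, 0.0, 0.4],
                [0.4, 0.5, 0.4, 0.0],
            ]
        )
        ids = ["a", "b", "c", "d"]
        tree = nj_tree(DistanceMatrix(ids=ids, d=d, m=np.ones((4, 4), int)))
        assert split_set(tree) == {frozenset({"c", "d"})}
        recovered = tree_distance_matrix(tree)
        assert np.allclose(recovered.d, d, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_additive_matrices_recovered(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        ids, D, want_splits = random_additive_matrix(n, rng)
        tree = nj_tree(DistanceMatrix(ids=ids, d=D, m=np.ones((n, n), int)))
        assert split_set(tree) == want_splits
        assert np.allclose(tree_distance_matrix(tree).d, D, atol=1e-9)

    def test_agrees_with_scikit_bio_nj(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(42)
        ids, D, _ = random_additive_matrix(8, rng)
        D_noisy = D + rng.uniform(-5e-3, 5e-3, size=D.shape)
        D_noisy = (D_noisy + D_noisy.T) / 2
        np.fill_diagonal(D_noisy, 0.0)
        ours = nj_tree(DistanceMatrix(ids=ids, d=D_noisy, m=np.ones_like(D, dtype=int)))
        theirs = skbio_nj(skbio.DistanceMatrix(D_noisy, ids))
        anchor = min(ids)
        their_splits = set()
        for node in theirs.non_tips(include_self=False):
            below = frozenset(t.name for t in node.tips())
            side = below if anchor not in below else frozenset(ids) - below
            if 2 <= len(side) <= len(ids) - 2:
                their_splits.add(side)
        assert split_set(ours) == their_splits

    def test_branch_lengths_non_negative(self):
        rng = np.random.default_rng(1)
        n = 7
        d = rng.uniform(0.0, 0.2, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        ids = [f"x{i}" for i in range(n)]
        tree = nj_tree(DistanceMatrix(ids=ids, d=d, m=np.ones((n, n), int)))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0.0

    def test_leaf_order_permutation_invariance_of_splits(self):
        rng = np.random.default_rng(6)
        ids, D, _ = random_additive_matrix(8, rng)
        tree1 = nj_tree(DistanceMatrix(ids=ids, d=D, m=np.ones_like(D, dtype=int)))
        perm = rng.permutation(len(ids))
        ids2 = [ids[k] for k in perm]
        D2 = D[np.ix_(perm, perm)]
        tree2 = nj_tree(DistanceMatrix(ids=ids2, d=D2, m=np.ones_like(D, dtype=int)))
        assert split_set(tree1) == split_set(tree2)

    def test_fewer_than_three_leaves_rejected(self):
        d = np.array([[0.0, 0.1], [0.1, 0.0]])
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(ids=["a", "b"], d=d, m=np.ones((2, 2), int)))


class TestMonophyly:
    def test_trivial_sets(self, small_survey):
        tree = nj_tree(p_distance_matrix(small_survey.alignment))
        ids = small_survey.alignment.ids
        assert is_monophyletic(tree, {ids[0]})
        assert is_monophyletic(tree, set(ids))

    def test_planted_subclades_form_clades(self, small_survey):
        tree = nj_tree(p_distance_matrix(small_survey.alignment))
        for label in small_survey.panel.labels:
            leaves = set(
                small_survey.truth[small_survey.truth.truth_label == label].clone_id
            )
            assert is_monophyletic(tree, leaves)

    def test_unknown_leaf_rejected(self, small_survey):
        tree = nj_tree(p_distance_matrix(small_survey.alignment))
        with pytest.raises(ValueError, match="bogus"):
            is_monophyletic(tree, {"bogus"})


class TestBootstrap:
    def test_supports_high_for_planted_subclades(self, small_survey):
        tree = bootstrap_supports(small_survey.alignment, reps=100, seed=3)
        for label in small_survey.panel.labels:
            leaves = set(
                small_survey.truth[small_survey.truth.truth_label == label].clone_id
            )
            assert split_support(tree, leaves) >= 95

    def test_supports_bounded_and_deterministic(self, small_survey):
        t1 = bootstrap_supports(small_survey.alignment, reps=100, seed=5)
        t2 = bootstrap_supports(small_survey.alignment, reps=100, seed=5)
        labels1 = sorted(
            n.label for n in t1.preorder_node_iter() if n.label is not None
        )
        labels2 = sorted(
            n.label for n in t2.preorder_node_iter() if n.label is not None
        )
        assert labels1 == labels2
        assert all(0 <= int(l) <= 100 for l in labels1)

    def test_identical_sequences_have_no_internal_splits(self):
        aln = AlignedSeqSet(ids=["a", "b", "c", "d"], rows=["ACGTACGT"] * 4)
        tree = bootstrap_supports(aln, reps=100, seed=1)
        assert split_set(tree) == set() or all(
            n.label is None for n in tree.preorder_internal_node_iter()
        )

    def test_low_reps_rejected(self, small_survey):
        with pytest.raises(ValueError):
            bootstrap_supports(small_survey.alignment, reps=50, seed=1)
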