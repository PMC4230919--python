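"""Masking and uncorrected p-distance behaviour, checked against a loop oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oophila.distances import (
    ColumnMask,
    UndefinedDistanceError,
    apply_mask,
    p_distance_matrix,
    p_distance_pair,
    subclade_range_table,
)
from oophila.io import AlignedSeqSet


def brute_force_p_distance(x: str, y: str):
    """Independent per-site loop oracle (written before the vectorized path)."""
    comparable = 0
    mismatches = 0
    for a, b in zip(x, y):
        if a in "ACGT" and b in "ACGT":
            comparable += 1
            if a != b:
                mismatches += 1
    return mismatches / comparable, comparable


class TestPairDistance:
    @pytest.mark.parametrize(
        "x,y,dist,m",
        [
            ("ACGT", "ACGA", 0.25, 4),
            ("AC-T", "ACGT", 0.0, 3),
            ("ACGT", "ACGT", 0.0, 4),
            ("ARGT", "AAGT", 0.0, 3),  # ambiguity code excluded, not matched
        ],
    )
    def test_hand_worked_pairs(self, x, y, dist, m):
        got = p_distance_pair(x, y)
        assert got.distance == pytest.approx(dist)
        assert got.comparable_sites == m

    def test_matches_loop_oracle_on_random_rows(self):
        rng = np.random.default_rng(0)
        alpha = list("ACGT-NR")
        for _ in range(20):
            x = "".join(rng.choice(alpha, size=500))
            y = "".join(rng.choice(alpha, size=500))
            want_d, want_m = brute_force_p_distance(x, y)
            got = p_distance_pair(x, y)
            assert got.distance == pytest.approx(want_d, abs=1e-15)
            assert got.comparable_sites == want_m

    def test_zero_comparable_sites_is_an_error(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance_pair("----", "ACGT")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            p_distance_pair("ACG", "ACGT")

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        x = "".join(rng.choice(list("ACGT-"), size=60))
        y = "".join(rng.choice(list("ACGT-"), size=60))
        try:
            dxy = p_distance_pair(x, y)
        except UndefinedDistanceError:
            return
        dyx = p_distance_pair(y, x)
        assert dxy == dyx
        assert 0.0 <= dxy.distance <= 1.0


class TestMatrix:
    def test_matches_brute_force_on_synthetic_survey(self, small_survey):
        aln = AlignedSeqSet(
            ids=small_survey.alignment.ids[:20], rows=small_survey.alignment.rows[:20]
        )
        dm = p_distance_matrix(aln)
        for i in range(20):
            for j in range(i + 1, 20):
                want_d, want_m = brute_force_p_distance(aln.rows[i], aln.rows[j])
                assert abs(dm.d[i, j] - want_d) < 1e-12
                assert dm.m[i, j] == want_m
        assert np.all(dm.d == dm.d.T)
        assert np.all(np.diag(dm.d) == 0)

    def test_gap_free_rows_have_full_comparable_counts(self, small_survey):
        dm = p_distance_matrix(small_survey.alignment)
        off = ~np.eye(len(dm), dtype=bool)
        assert np.all(dm.m[off] == small_survey.alignment.length)

    def test_identical_sequences_give_zero_matrix(self):
        aln = AlignedSeqSet(ids=["a", "b", "c"], rows=["ACGT"] * 3)
        assert np.all(p_distance_matrix(aln).d == 0.0)

    def test_label_permutation_permutes_matrix(self, tiny_alignment):
        dm = p_distance_matrix(tiny_alignment)
        perm = AlignedSeqSet(
            ids=list(reversed(tiny_alignment.ids)),
            rows=list(reversed(tiny_alignment.rows)),
        )
        dm2 = p_distance_matrix(perm)
        for a in tiny_alignment.ids:
            for b in tiny_alignment.ids:
                if a != b:
                    assert dm.get(a, b) == pytest.approx(dm2.get(a, b))

    def test_undefined_pair_lists_ids(self):
        aln = AlignedSeqSet(ids=["a", "b", "c"], rows=["A---", "-C--", "ACGT"])
        with pytest.raises(UndefinedDistanceError, match="'a', 'b'"):
            p_distance_matrix(aln)


class TestMask:
    def test_identity_mask(self, tiny_alignment):
        mask = ColumnMask(keep=tuple(range(tiny_alignment.length)))
        out = apply_mask(tiny_alignment, mask)
        assert out.rows == tiny_alignment.rows

    def test_empty_mask_keeps_ids(self, tiny_alignment):
        out = apply_mask(tiny_alignment, ColumnMask(keep=()))
        assert out.ids == tiny_alignment.ids
        assert out.length == 0

    def test_column_selection(self):
        aln = AlignedSeqSet(ids=["a"], rows=["ACGT"])
        assert apply_mask(aln, ColumnMask(keep=(0, 2))).rows == ["AG"]

    def test_out_of_range_index_named(self, tiny_alignment):
        with pytest.raises(IndexError, match="99"):
            apply_mask(tiny_alignment, ColumnMask(keep=(0, 99)))

    def test_from_ranges_is_1_based_inclusive(self):
        mask = ColumnMask.from_ranges([(1, 3), (6, 6)])
        assert mask.keep == (0, 1, 2, 5)

    def test_mask_file_round_trip(self, tmp_path):
        path = tmp_path / "mask.txt"
        path.write_text("1\t3\n6\t6\n")
        assert ColumnMask.from_file(path).keep == (0, 1, 2, 5)

    def test_masking_shift_is_bounded_by_removed_mass(self):
        rng = np.random.default_rng(3)
        x = "".join(rng.choice(list("ACGT"), size=200))
        y = "".join(rng.choice(list("ACGT"), size=200))
        aln = AlignedSeqSet(ids=["x", "y"], rows=[x, y])
        keep = tuple(range(150))
        masked = apply_mask(aln, ColumnMask(keep=keep))
        d_full = p_distance_pair(x, y).distance
        d_masked = p_distance_pair(masked.rows[0], masked.rows[1]).distance
        assert abs(d_masked - d_full) <= 50 / 150


class TestRangeTable:
    def test_constructed_two_group_cell(self):
        # two groups of identical members at exact cross distance 0.03
        base = "A" * 100
        other = "C" * 3 + "A" * 97
        aln = AlignedSeqSet(ids=["g1a", "g1b", "g2a", "g2b"], rows=[base, base, other, other])
        dm = p_distance_matrix(aln)
        table = subclade_range_table(
            dm, {"g1a": "G1", "g1b": "G1", "g2a": "G2", "g2b": "G2"}
        )
        assert table.cell("G1", "G2") == (3.0, 3.0)
        assert table.format_cell("G1", "G2") == "3.00-3.00%"
        assert table.cell("G1", "G1") == (0.0, 0.0)

    def test_single_group_all_zero(self):
        aln = AlignedSeqSet(ids=["a", "b", "c"], rows=["ACGT"] * 3)
        table = subclade_range_table(
            p_distance_matrix(aln), {"a": "G", "b": "G", "c": "G"}
        )
        assert table.cell("G", "G") == (0.0, 0.0)

    def test_singleton_within_cell_is_na(self):
        aln = AlignedSeqSet(ids=["a", "b"], rows=["ACGT", "ACGA"])
        table = subclade_range_table(p_distance_matrix(aln), {"a": "G1", "b": "G2"})
        assert table.cell("G1", "G1") is None
        assert table.format_cell("G1", "G1") == "NA"

    def test_between_cells_bracket_panel_divergences(self, small_survey):
        dm = p_distance_matrix(small_survey.alignment)
        truth = dict(
            zip(small_survey.truth.clone_id, small_survey.truth.truth_label)
        )
        table = subclade_range_table(dm, truth)
        realized = small_survey.panel.realized_divergence()
        labels = list(small_survey.panel.labels)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                lo, hi = table.cell(a, b)
                target = 100.0 * realized[labels.index(a), labels.index(b)]
                assert lo <= target <= hi or abs(lo - target) < 1.0

    def test_ungrouped_id_rejected(self, tiny_alignment):
        with pytest.raises(ValueError, match="'c'"):
            subclade_range_table(
                p_distance_matrix(tiny_alignment), {"a": "G", "b": "G"}
            )
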