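import itertools
import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from favat.errors import VotingError
from favat.profile_io import Profile, make_profile
from favat.tripalign import ThreeAlignment
from favat.voting import (
    ScoreEntry,
    ScoreTable,
    merge_votes,
    normalize,
    select_candidates,
    t_scores,
    top_positions,
    v_score,
)

RESIDUES = "ARNDCQEGHILKMFPSTWYV"


def gapless_alignment(target, a_rows, na_rows):
    """Hand-built three-way alignment from equal-length row strings."""
    length = len(target)
    assert all(len(r) == length for r in a_rows + na_rows)
    t = Profile(("t",), (target,), (1.0,), label="target", allow_gap_columns=True)
    a = Profile(
        tuple(f"a{i}" for i in range(len(a_rows))),
        tuple(a_rows),
        (1.0,) * len(a_rows),
        label="A",
        allow_gap_columns=True,
    )
    na = Profile(
        tuple(f"n{i}" for i in range(len(na_rows))),
        tuple(na_rows),
        (1.0,) * len(na_rows),
        label="~A",
        allow_gap_columns=True,
    )
    shapes = tuple(
        "".join(
            "-" if all(s[col] == "-" for s in p.sequences) else "r"
            for p in (t, a, na)
        )
        for col in range(length)
    )
    return ThreeAlignment(profiles=(t, a, na), score=0.0, column_types=shapes)


class TestVScore:
    def test_worked_example(self, blosum62):
        assert v_score("A", "H", "L", blosum62) == -1

    def test_two_lookups(self, blosum62):
        assert v_score("L", "L", "Y", blosum62) == 4 - (-1)

    def test_identical_votes_cancel(self, blosum62):
        for t, x in itertools.product("AHLKY", repeat=2):
            assert v_score(t, x, x, blosum62) == 0

    def test_antisymmetry_exhaustive(self, blosum62):
        for t, x, y in itertools.product(RESIDUES, repeat=3):
            assert v_score(t, x, y, blosum62) == -v_score(t, y, x, blosum62)

    def test_gap_target_rejected(self, blosum62):
        with pytest.raises(VotingError, match="gap"):
            v_score("-", "A", "L", blosum62)

    def test_group_gap_zeroes_one_term(self, blosum62):
        assert v_score("A", "-", "L", blosum62) == 0 - (-1)
        assert v_score("A", "H", "-", blosum62) == -2


class TestTScores:
    def test_single_pair_column_equals_v_score(self, blosum62):
        aln = gapless_alignment("A", ["H"], ["L"])
        table = t_scores(aln, blosum62)
        assert table.entries[0].raw_t == -1

    def test_any_gap_in_any_group_zeroes_column(self, blosum62):
        aln = gapless_alignment("AL", ["HL", "H-"], ["LY", "LY"])
        table = t_scores(aln, blosum62, gap_rule="any_gap_zero")
        assert table.entries[1].raw_t == 0
        assert table.entries[1].gap_zeroed
        assert not table.entries[0].gap_zeroed

    def test_target_gap_skip_still_scores_gapped_column(self, blosum62):
        aln = gapless_alignment("L", ["-"], ["Y"])
        table = t_scores(aln, blosum62, gap_rule="target_gap_skip")
        # gap A-term contributes 0; -M(L,Y) remains
        assert table.entries[0].raw_t == 1
        assert not table.entries[0].gap_zeroed

    def test_four_vote_column(self, blosum62):
        aln = gapless_alignment("L", ["L", "K"], ["Y", "Y"])
        table = t_scores(aln, blosum62)
        # votes: (L,L,Y)=5 twice, (L,K,Y)=-1 twice
        assert table.entries[0].raw_t == 5 + 5 + (-1) + (-1)
        assert table.entries[0].raw_t == sum(
            v_score("L", a, b, blosum62) for a in "LK" for b in "YY"
        )

    def test_target_gap_columns_not_reported(self, blosum62):
        aln = gapless_alignment("A-L", ["HHH"], ["LLL"])
        table = t_scores(aln, blosum62)
        assert [e.position for e in table.entries] == [1, 2]
        assert [e.residue for e in table.entries] == ["A", "L"]

    def test_swapping_group_labels_negates_raw_scores(self, blosum62):
        rng = np.random.default_rng(3)
        target = "".join(rng.choice(list(RESIDUES), size=8))
        a_rows = ["".join(rng.choice(list(RESIDUES), size=8)) for _ in range(2)]
        na_rows = ["".join(rng.choice(list(RESIDUES), size=8)) for _ in range(3)]
        aln = gapless_alignment(target, a_rows, na_rows)
        fwd = t_scores(aln, blosum62)
        rev = t_scores(aln, blosum62, a_label="~A", na_label="A")
        for e1, e2 in zip(fwd.entries, rev.entries):
            assert e1.raw_t == -e2.raw_t

    def test_multi_sequence_target_rejected(self, blosum62):
        t = Profile(("a", "b"), ("AA", "AA"), (1.0, 1.0), label="target")
        other = Profile(("c",), ("AA",), (1.0,), label="A")
        third = Profile(("d",), ("AA",), (1.0,), label="~A")
        aln = ThreeAlignment((t, other, third), 0.0, ("rrr", "rrr"))
        with pytest.raises(VotingError, match="single target"):
            t_scores(aln, blosum62)

    def test_missing_group_labels_rejected(self, blosum62):
        aln = gapless_alignment("A", ["H"], ["L"])
        with pytest.raises(VotingError, match="labelled"):
            t_scores(aln, blosum62, a_label="group3", na_label="group2")

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.data())
    def test_double_sum_oracle_on_random_columns(self, blosum62, data):
        """Raw column score equals the direct double sum over all m*n pairs."""
        res = st.sampled_from(RESIDUES)
        m = data.draw(st.integers(1, 4))
        n = data.draw(st.integers(1, 4))
        length = data.draw(st.integers(1, 6))
        target = "".join(data.draw(st.lists(res, min_size=length, max_size=length)))
        a_rows = [
            "".join(data.draw(st.lists(res, min_size=length, max_size=length)))
            for _ in range(m)
        ]
        na_rows = [
            "".join(data.draw(st.lists(res, min_size=length, max_size=length)))
            for _ in range(n)
        ]
        aln = gapless_alignment(target, a_rows, na_rows)
        table = t_scores(aln, blosum62)
        for col, entry in enumerate(table.entries):
            direct = sum(
                blosum62.score(target[col], a[col])
                - blosum62.score(target[col], b[col])
                for a in a_rows
                for b in na_rows
            )
            assert entry.raw_t == pytest.approx(direct)


def table_from_raw(raws, residue="A"):
    entries = tuple(
        ScoreEntry(i + 1, residue, float(r)) for i, r in enumerate(raws)
    )
    return ScoreTable(entries=entries, min_raw=min(raws), max_raw=max(raws))


class TestNormalize:
    def test_formula(self):
        table = normalize(table_from_raw([0, 4, 8]))
        assert [e.norm_t for e in table.entries] == [0.0, 50.0, 100.0]

    def test_degenerate_range_warns_and_zeroes(self, caplog):
        with caplog.at_level(logging.WARNING, logger="favat.voting"):
            table = normalize(table_from_raw([3, 3, 3]))
        assert all(e.norm_t == 0.0 for e in table.entries)
        assert any("equal" in r.message for r in caplog.records)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        raws=st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=50
        ).filter(lambda xs: max(xs) > min(xs))
    )
    def test_endpoints_and_range(self, raws):
        table = normalize(table_from_raw(raws))
        norms = [e.norm_t for e in table.entries]
        assert all(0.0 <= v <= 100.0 for v in norms)
        assert norms[raws.index(min(raws))] == 0.0
        assert norms[raws.index(max(raws))] == 100.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        raws=st.lists(
            st.floats(-1e3, 1e3, allow_nan=False), min_size=2, max_size=20
        ).filter(lambda xs: max(xs) > min(xs)),
        scale=st.floats(0.01, 100),
        shift=st.floats(-1e3, 1e3),
    )
    def test_invariant_under_positive_affine_transform(self, raws, scale, shift):
        base = normalize(table_from_raw(raws))
        moved = normalize(table_from_raw([scale * r + shift for r in raws]))
        for e1, e2 in zip(base.entries, moved.entries):
            assert e1.norm_t == pytest.approx(e2.norm_t, abs=1e-6)


class TestSelectionAndMerging:
    def make_normalized(self, mapping):
        raws = [mapping[k] for k in sorted(mapping)]
        entries = tuple(
            ScoreEntry(pos, "A", raw_t=val, norm_t=float(val))
            for pos, val in sorted(mapping.items())
        )
        return ScoreTable(
            entries=entries, min_raw=min(raws), max_raw=max(raws), normalized=True
        )

    def test_selection_sorted_and_strict(self):
        table = self.make_normalized({10: 65.0, 20: 59.9, 30: 80.0})
        got = select_candidates(table, 60)
        assert [(p, s) for p, _, s in got] == [(30, 80.0), (10, 65.0)]
        assert select_candidates(table, 100) == []
        assert len(select_candidates(table, 0)) == 3

    def test_selection_requires_normalized_table(self):
        table = table_from_raw([0, 1, 2])
        with pytest.raises(VotingError, match="normalized"):
            select_candidates(table, 60)

    def test_merge_requires_exceeding_both(self):
        t1 = self.make_normalized({5: 65.0, 6: 65.0})
        t2 = self.make_normalized({5: 70.0, 6: 50.0})
        assert merge_votes(t1, t2, 60) == [5]

    def test_merge_rejects_different_targets(self):
        t1 = self.make_normalized({5: 65.0})
        entries = (ScoreEntry(5, "W", 65.0, 65.0),)
        t2 = ScoreTable(entries=entries, min_raw=65.0, max_raw=65.0, normalized=True)
        with pytest.raises(VotingError, match="same target"):
            merge_votes(t1, t2, 60)

    def test_top_positions_ties_break_by_position(self):
        table = self.make_normalized({1: 50.0, 2: 50.0, 3: 80.0})
        assert top_positions(table, 2) == [3, 1]
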