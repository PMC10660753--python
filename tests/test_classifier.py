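"""Structural classification and anticodon-vicinity selection."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trfquant import (
    ClassLabel,
    CodingCoords,
    NotAFragmentError,
    Placement,
    classify,
    half_end_positions,
    to_coding_coords,
    vicinity_select,
)
from conftest import profile_of


def truth_table(c_start, c_end, s, L, space="mature"):
    """Independently coded classification oracle (range arithmetic form)."""
    if space == "precursor" and c_start <= -1:
        return "5'U-tRF"
    if space == "precursor" and c_end > L:
        return "tRF-1"
    if c_start in (0, 1) and c_end == L + 3:
        return "reject"
    if L + 1 <= c_end <= L + 3:
        return "3'-tRH" if s <= c_start <= s + 3 else "3'-tRF"
    if c_start in (0, 1):
        return "5'-tRH" if s - 1 <= c_end <= s + 2 else "5'-tRF"
    return "i-tRF"


def run_classify(c_start, c_end, s, L, space="mature"):
    try:
        return classify(CodingCoords(c_start, c_end, s, L, space)).value
    except NotAFragmentError:
        return "reject"


class TestCoords:
    def test_identity_shift_without_minus1(self, lys_pair):
        t = lys_pair["trna10_LysCTT"]
        c = to_coding_coords(Placement(t.transcript_id, 1, 33), t)
        assert (c.c_start, c.c_end, c.s, c.L) == (1, 33, 34, 73)

    def test_minus1_shift_on_his(self, his_single):
        (t,) = his_single.values()
        assert t.has_minus1
        c = to_coding_coords(Placement(t.transcript_id, 1, 34), t)
        assert (c.c_start, c.c_end) == (0, 33)

    def test_cca_end_maps_to_L_plus_3(self, lys_pair):
        t = lys_pair["trna10_LysCTT"]
        c = to_coding_coords(Placement(t.transcript_id, 40, len(t.sequence)), t)
        assert c.c_end == t.L + 3


class TestHalfEnds:
    @pytest.mark.parametrize(
        "s,expected",
        [(34, {33, 34, 35, 36}), (33, {32, 33, 34, 35})],
    )
    def test_four_cleavage_positions(self, s, expected):
        assert half_end_positions(s) == expected

    @given(st.integers(min_value=2, max_value=200))
    @settings(derandomize=True)
    def test_always_four_consecutive(self, s):
        ends = half_end_positions(s)
        assert len(ends) == 4 and sorted(ends) == list(range(s - 1, s + 3))

    def test_s_below_2_rejected(self):
        with pytest.raises(ValueError):
            half_end_positions(1)


class TestClassify:
    @pytest.mark.parametrize(
        "c_start,c_end,space,expected",
        [
            (1, 33, "mature", ClassLabel.FIVE_TRH),    # one nt before the anticodon
            (1, 27, "mature", ClassLabel.FIVE_TRF),
            (0, 33, "mature", ClassLabel.FIVE_TRH),    # -1 start
            (2, 73, "mature", ClassLabel.I_TRF),
            (34, 76, "mature", ClassLabel.THREE_TRH),  # begins where 5'-tRHs end
            (5, 75, "mature", ClassLabel.THREE_TRF),
            (-4, 20, "precursor", ClassLabel.FIVE_U_TRF),
            (60, 80, "precursor", ClassLabel.TRF_1),
        ],
    )
    def test_examples_L73_s34(self, c_start, c_end, space, expected):
        assert classify(CodingCoords(c_start, c_end, 34, 73, space)) is expected

    def test_full_length_rejected(self):
        with pytest.raises(NotAFragmentError):
            classify(CodingCoords(1, 76, 34, 73))
        with pytest.raises(NotAFragmentError):
            classify(CodingCoords(0, 76, 34, 73))

    def test_exactly_seven_labels(self):
        assert len(ClassLabel) == 7

    def test_agrees_with_truth_table_small(self):
        for L in range(4, 41):
            for s in range(2, L - 1):
                for c_start in range(0, L + 4):
                    for c_end in range(c_start, L + 4):
                        assert run_classify(c_start, c_end, s, L) == truth_table(
                            c_start, c_end, s, L
                        )

    @given(
        L=st.integers(min_value=10, max_value=150),
        data=st.data(),
    )
    @settings(derandomize=True, max_examples=300)
    def test_precursor_space_agrees_with_truth_table(self, L, data):
        s = data.draw(st.integers(min_value=2, max_value=L - 2))
        c_start = data.draw(st.integers(min_value=-10, max_value=L + 3))
        c_end = data.draw(st.integers(min_value=c_start, max_value=L + 10))
        assert run_classify(c_start, c_end, s, L, "precursor") == truth_table(
            c_start, c_end, s, L, "precursor"
        )


def five_prime_fragments(t, min_len=16, max_len=50):
    """All 5'-anchored fragment sequences of a transcript."""
    return [
        t.sequence[:k]
        for k in range(min_len, min(max_len, len(t.sequence) - 1) + 1)
    ]


class TestVicinitySelect:
    def test_window7_spans_27_to_41(self, lys_pair, lys_index):
        t = lys_pair["trna10_LysCTT"]  # s = 34, no -1 extension
        profile = profile_of(lys_index, five_prime_fragments(t))
        selected = vicinity_select(profile, lys_pair, window=7)
        lengths = sorted(s.row.length for s in selected)
        assert lengths == list(range(27, 42))
        labels = {s.row.length: s.label for s in selected}
        assert {k for k, v in labels.items() if v is ClassLabel.FIVE_TRH} == {33, 34, 35, 36}

    def test_beyond_window_excluded(self, lys_pair, lys_index):
        t = lys_pair["trna10_LysCTT"]
        profile = profile_of(lys_index, [t.sequence[: 34 - 8]])  # c_end = s - 8
        assert vicinity_select(profile, lys_pair, window=7) == []

    def test_his_minus1_length_arithmetic(self, his_single):
        from trfquant import FragmentIndex

        (t,) = his_single.values()
        idx = FragmentIndex([t], min_len=16, max_len=50)
        profile = profile_of(idx, five_prime_fragments(t))
        selected = vicinity_select(profile, his_single, window=7)
        s_coding = t.a_start - 1  # coding-relative anticodon start
        by_cend = {sel.placements[0].coords.c_end: sel for sel in selected}
        sel = by_cend[s_coding + 7]
        # -1 start: mature length is c_end + 1
        assert sel.row.length == s_coding + 7 + 1
        assert min(by_cend) == s_coding - 7 and max(by_cend) == s_coding + 7

    def test_ambiguous_rows_kept_with_all_placements(self, lys_pair, lys_index):
        t10 = lys_pair["trna10_LysCTT"]
        profile = profile_of(lys_index, [t10.sequence[:28]])  # shared 28-mer
        (sel,) = vicinity_select(profile, lys_pair, window=7)
        assert sel.source_label == "trna10_LysCTT|trna119_LysCTT"
        assert len(sel.placements) == 2

    def test_window_below_2_rejected(self, lys_pair, lys_index):
        profile = profile_of(lys_index, [lys_pair["trna10_LysCTT"].sequence[:30]])
        with pytest.raises(ValueError):
            vicinity_select(profile, lys_pair, window=1)

    def test_exactly_four_5prime_anchored_halves_per_transcript(
        self, lys_pair, glu_pair, lys_index
    ):
        from trfquant import FragmentIndex

        for space in (lys_pair, glu_pair):
            idx = FragmentIndex(space.values(), min_len=16, max_len=50)
            for t in space.values():
                profile = profile_of(idx, five_prime_fragments(t))
                selected = vicinity_select(profile, space, window=7)
                n_trh = sum(
                    1
                    for sel in selected
                    for q in sel.placements
                    if q.placement.transcript_id == t.transcript_id
                    and q.label is ClassLabel.FIVE_TRH
                )
                assert n_trh == 4
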