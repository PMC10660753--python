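"""Structural classification of tRF placements and anticodon-vicinity selection.

Seven structural classes are distinguished by fragment endpoints relative to
the tRNA coding sequence (coding-relative frame: first coding nt = 1, the
position one before it = 0, CCA tail = L+1..L+3):

* 5'U-tRF — precursor fragment starting in the 5' leader (c_start <= -1);
* tRF-1   — precursor fragment ending in the 3' trailer (c_end > L);
* 3'-tRH  — 3' tRNA half: ends in C/CC/CCA of the CCA tail and starts where
  5' halves end (c_start in {s..s+3}, s = anticodon start);
* 3'-tRF  — any other fragment ending in the CCA tail;
* 5'-tRH  — 5' tRNA half: anchored at the 5' end (c_start in {0, 1}) with its
  3' end at one of the four half cleavage positions {s-1, s, s+1, s+2};
* 5'-tRF  — any other 5'-anchored fragment;
* i-tRF   — both endpoints strictly inside the coding sequence.

The vicinity selection keeps 5'-anchored fragments whose 3' end lies within
a window (default +/-7 nt) of the anticodon start — the 5'-tRHs together
with the "long" 5'-tRFs that flank them; with the default window and no -1
extension these fragments span 27-41 nt for a typical anticodon start of 34.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Literal, Mapping, NamedTuple, Sequence

from .fragment_index import Placement
from .profiler import Profile, ProfileRow
from .reference import MatureTranscript

__all__ = [
    "ClassLabel",
    "CodingCoords",
    "NotAFragmentError",
    "to_coding_coords",
    "half_end_positions",
    "classify",
    "vicinity_select",
    "SelectedFragment",
    "QualifiedPlacement",
    "write_classified",
]


class ClassLabel(str, Enum):
    """The seven structural tRF classes."""

    FIVE_U_TRF = "5'U-tRF"
    FIVE_TRF = "5'-tRF"
    FIVE_TRH = "5'-tRH"
    I_TRF = "i-tRF"
    THREE_TRH = "3'-tRH"
    THREE_TRF = "3'-tRF"
    TRF_1 = "tRF-1"


class NotAFragmentError(ValueError):
    """The placement spans the full-length mature molecule — not a fragment."""


class CodingCoords(NamedTuple):
    """Fragment endpoints in the coding-relative frame.

    ``s`` is the coding-relative anticodon start, ``L`` the coding length.
    ``space`` is "mature" for placements on the mature transcript and
    "precursor" when leader/trailer positions (< 0 or > L+3) are possible.
    """

    c_start: int
    c_end: int
    s: int
    L: int
    space: str = "mature"


def to_coding_coords(placement: Placement, transcript: MatureTranscript) -> CodingCoords:
    """Convert a mature-linear placement to coding-relative coordinates."""
    shift = transcript.shift
    return CodingCoords(
        c_start=placement.start - shift,
        c_end=placement.end - shift,
        s=transcript.a_start - shift,
        L=transcript.L,
        space="mature",
    )


def half_end_positions(s: int) -> set[int]:
    """The four 3'-terminal coding positions of a 5'-tRH.

    Cleavage one nt before the anticodon, at its start, after its first nt,
    or after its second nt: {s-1, s, s+1, s+2}.
    """
    if s < 2:
        raise ValueError(f"anticodon start s={s} < 2")
    return {s - 1, s, s + 1, s + 2}


def classify(coords: CodingCoords) -> ClassLabel:
    """Assign the structural class for one placement; first matching rule wins."""
    c_start, c_end, s, L, space = coords
    if c_start > c_end:
        raise ValueError(f"empty fragment span {c_start}..{c_end}")
    if space == "precursor" and c_start <= -1:
        return ClassLabel.FIVE_U_TRF
    if space == "precursor" and c_end > L:
        return ClassLabel.TRF_1
    # full-length molecule: caught before the CCA-anchored rules so it is
    # rejected rather than silently labeled 3'-tRF
    if c_start in (0, 1) and c_end == L + 3:
        raise NotAFragmentError(
            f"span {c_start}..{c_end} covers the full mature molecule (L={L})"
        )
    if L + 1 <= c_end <= L + 3:
        if s <= c_start <= s + 3:
            return ClassLabel.THREE_TRH
        return ClassLabel.THREE_TRF
    if c_start in (0, 1):
        if c_end in half_end_positions(s):
            return ClassLabel.FIVE_TRH
        return ClassLabel.FIVE_TRF
    return ClassLabel.I_TRF


class QualifiedPlacement(NamedTuple):
    """A placement passing the vicinity filter, with its coords and class."""

    placement: Placement
    coords: CodingCoords
    label: ClassLabel


@dataclass(frozen=True)
class SelectedFragment:
    """A profile row retained by the vicinity selection.

    ``label`` is 5'-tRH if any qualifying placement is a half, else 5'-tRF
    ("long" 5'-tRF); ``source_label`` joins the qualifying transcript ids
    with "|" so ambiguous rows are visibly multi-source.
    """

    row: ProfileRow
    placements: tuple[QualifiedPlacement, ...]

    @property
    def label(self) -> ClassLabel:
        if any(q.label is ClassLabel.FIVE_TRH for q in self.placements):
            return ClassLabel.FIVE_TRH
        return ClassLabel.FIVE_TRF

    @property
    def source_label(self) -> str:
        return "|".join(sorted({q.placement.transcript_id for q in self.placements}))


def vicinity_select(
    profile: Profile,
    transcripts: Mapping[str, MatureTranscript],
    window: int = 7,
) -> list[SelectedFragment]:
    """Select 5'-anchored fragments whose 3' end is near the anticodon start.

    Keeps rows of the profile's analysis set having at least one placement
    with c_start in {0, 1} and c_end in [s-window, s+window]; rows are kept
    regardless of exclusivity, carrying all qualifying placements.
    """
    if window < 2:
        raise ValueError(
            f"window {window} < 2 would exclude some 5'-tRH endpoints"
        )
    selected: list[SelectedFragment] = []
    for row in profile.analysis_rows:
        qualifying: list[QualifiedPlacement] = []
        for p in row.placements:
            t = transcripts.get(p.transcript_id)
            if t is None:
                raise KeyError(f"placement on unknown transcript {p.transcript_id!r}")
            coords = to_coding_coords(p, t)
            if coords.c_start in (0, 1) and (
                coords.s - window <= coords.c_end <= coords.s + window
            ):
                try:
                    label = classify(coords)
                except NotAFragmentError:
                    continue
                qualifying.append(QualifiedPlacement(p, coords, label))
        if qualifying:
            selected.append(SelectedFragment(row=row, placements=tuple(qualifying)))
    return selected


def classify_profile(
    profile: Profile,
    transcripts: Mapping[str, MatureTranscript],
) -> list[tuple[ProfileRow, tuple[QualifiedPlacement, ...]]]:
    """Classify every placement of every analysis row (no vicinity filter).

    Full-length placements are dropped (they are not fragments).
    """
    out = []
    for row in profile.analysis_rows:
        items: list[QualifiedPlacement] = []
        for p in row.placements:
            t = transcripts[p.transcript_id]
            coords = to_coding_coords(p, t)
            try:
                label = classify(coords)
            except NotAFragmentError:
                continue
            items.append(QualifiedPlacement(p, coords, label))
        out.append((row, tuple(items)))
    return out


def write_classified(
    classified: Sequence[tuple[ProfileRow, tuple[QualifiedPlacement, ...]]]
    | Sequence[SelectedFragment],
    path,
) -> None:
    """Write a classified/selected profile TSV.

    Adds class, c_start, c_end, s columns (semicolon-joined across
    placements) to the basic profile columns.
    """
    with open(path, "w") as fh:
        fh.write(
            "sequence\tlength\traw_count\trpm\texclusivity\t"
            "placements\tclass\tc_start\tc_end\ts\n"
        )
        for item in classified:
            if isinstance(item, SelectedFragment):
                row, quals = item.row, item.placements
            else:
                row, quals = item
            pl = ";".join(
                f"{q.placement.transcript_id}:{q.placement.start}-{q.placement.end}"
                for q in quals
            )
            cls = ";".join(q.label.value for q in quals)
            cs = ";".join(str(q.coords.c_start) for q in quals)
            ce = ";".join(str(q.coords.c_end) for q in quals)
            ss = ";".join(str(q.coords.s) for q in quals)
            fh.write(
                f"{row.sequence}\t{row.length}\t{row.raw_count}\t{row.rpm:.4f}\t"
                f"{row.exclusivity.value}\t{pl}\t{cls}\t{cs}\t{ce}\t{ss}\n"
            )
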