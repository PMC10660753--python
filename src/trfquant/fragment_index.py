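"""Exhaustive fragment index over mature tRNA space.

Every distinct substring of any mature transcript with length in
[min_len, max_len] is recorded once, with the full list of its placements
and an *exclusivity* level saying how precisely the fragment pins down its
source: a single transcript, a single isodecoder group, a single isoacceptor
group, or none of those (ambiguous).  Because each distinct sequence has
exactly one entry, read counting against the index can never double-count
a molecule across the transcripts that contain it.

An optional genome scan flags fragments that also occur, on either strand,
outside annotated tRNA loci — candidate false positives whose reads may not
be tRNA-derived at all.  Fragments spanning the non-templated CCA tail or
the post-transcriptional -1 G are searched as-is and are typically
genome-absent, hence unflagged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .reference import MatureTranscript

__all__ = [
    "Placement",
    "Exclusivity",
    "FragmentAnnotation",
    "FragmentIndex",
    "build_index",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Placement:
    """One occurrence of a fragment: mature-linear 1-based inclusive span."""

    transcript_id: str
    start: int
    end: int


class Exclusivity(str, Enum):
    UNIQUE_TRANSCRIPT = "unique_transcript"
    UNIQUE_ISODECODER = "unique_isodecoder"
    UNIQUE_ISOACCEPTOR = "unique_isoacceptor"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class FragmentAnnotation:
    sequence: str
    placements: tuple[Placement, ...]
    exclusivity: Exclusivity
    genome_flag: bool | None = None


def _exclusivity(
    placements: Iterable[Placement],
    transcripts: Mapping[str, MatureTranscript],
) -> Exclusivity:
    tids = {p.transcript_id for p in placements}
    if len(tids) == 1:
        return Exclusivity.UNIQUE_TRANSCRIPT
    if len({transcripts[t].isodecoder_key for t in tids}) == 1:
        return Exclusivity.UNIQUE_ISODECODER
    if len({transcripts[t].isoacceptor_key for t in tids}) == 1:
        return Exclusivity.UNIQUE_ISOACCEPTOR
    return Exclusivity.AMBIGUOUS


class FragmentIndex:
    """Lookup structure mapping fragment sequence -> :class:`FragmentAnnotation`.

    Content is deterministic and independent of transcript input order:
    placements are sorted by (transcript_id, start, end).
    """

    def __init__(
        self,
        transcripts: Iterable[MatureTranscript],
        min_len: int = 16,
        max_len: int = 50,
    ) -> None:
        if not (1 <= min_len <= max_len):
            raise ValueError(f"invalid length bounds [{min_len}, {max_len}]")
        self.min_len = min_len
        self.max_len = max_len
        self.transcripts: dict[str, MatureTranscript] = {
            t.transcript_id: t for t in sorted(transcripts, key=lambda t: t.transcript_id)
        }

        raw: dict[str, list[Placement]] = {}
        for tid, t in self.transcripts.items():
            n = len(t.sequence)
            for length in range(min_len, min(max_len, n) + 1):
                for start0 in range(n - length + 1):
                    frag = t.sequence[start0 : start0 + length]
                    raw.setdefault(frag, []).append(
                        Placement(tid, start0 + 1, start0 + length)
                    )

        self.fragments: dict[str, FragmentAnnotation] = {}
        for seq, places in raw.items():
            places.sort()
            self.fragments[seq] = FragmentAnnotation(
                sequence=seq,
                placements=tuple(places),
                exclusivity=_exclusivity(places, self.transcripts),
            )

    def __len__(self) -> int:
        return len(self.fragments)

    def __contains__(self, seq: str) -> bool:
        return seq in self.fragments

    def lookup(self, seq: str) -> FragmentAnnotation | None:
        """Exact full-string lookup; ``None`` for any absent sequence."""
        return self.fragments.get(seq)

    # -- genome false-positive flagging -------------------------------------

    def flag_genome(
        self,
        genome_fasta: str | Path,
        trna_bed: str | Path,
    ) -> None:
        """Set ``genome_flag`` on every fragment.

        A fragment is flagged iff it (or its reverse complement) occurs as an
        exact substring of the genome at a location not fully contained in any
        tRNA-locus BED interval (0-based half-open).  Zero flank tolerance.
        """
        contigs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(genome_fasta), "fasta")
        }
        loci: dict[str, list[tuple[int, int]]] = {}
        with open(trna_bed) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                if chrom not in contigs:
                    raise ValueError(f"BED interval on unknown contig {chrom!r}")
                if start < 0 or end > len(contigs[chrom]):
                    raise ValueError(
                        f"BED interval {chrom}:{start}-{end} beyond contig bounds"
                    )
                loci.setdefault(chrom, []).append((start, end))

        def covered(chrom: str, s: int, e: int) -> bool:
            return any(ls <= s and e <= le for ls, le in loci.get(chrom, ()))

        for seq, ann in self.fragments.items():
            flagged = False
            for query in {seq, reverse_complement(seq)}:
                for chrom, contig in contigs.items():
                    i = contig.find(query)
                    while i >= 0:
                        if not covered(chrom, i, i + len(query)):
                            flagged = True
                            break
                        i = contig.find(query, i + 1)
                    if flagged:
                        break
                if flagged:
                    break
            self.fragments[seq] = replace(ann, genome_flag=flagged)

    # -- serialization -------------------------------------------------------

    def write_tsv(self, path: str | Path) -> None:
        """Serialize as a TSV: sequence, placements (tid:start-end;...), exclusivity."""
        with open(path, "w") as fh:
            fh.write("sequence\tplacements\texclusivity\n")
            for seq in sorted(self.fragments):
                ann = self.fragments[seq]
                pl = ";".join(
                    f"{p.transcript_id}:{p.start}-{p.end}" for p in ann.placements
                )
                fh.write(f"{seq}\t{pl}\t{ann.exclusivity.value}\n")

    @staticmethod
    def read_tsv(path: str | Path) -> dict[str, FragmentAnnotation]:
        """Read back the serialized form as a plain sequence -> annotation dict."""
        out: dict[str, FragmentAnnotation] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("sequence\t"):
                raise ValueError(f"{path}: not a serialized fragment index")
            for line in fh:
                seq, pl, excl = line.rstrip("\n").split("\t")
                placements = []
                for item in pl.split(";"):
                    tid, span = item.rsplit(":", 1)
                    s, e = span.split("-")
                    placements.append(Placement(tid, int(s), int(e)))
                out[seq] = FragmentAnnotation(
                    sequence=seq,
                    placements=tuple(placements),
                    exclusivity=Exclusivity(excl),
                )
        return out


def build_index(
    transcripts: Iterable[MatureTranscript],
    min_len: int = 16,
    max_len: int = 50,
) -> FragmentIndex:
    """Build the exhaustive fragment index (functional alias for the class)."""
    return FragmentIndex(transcripts, min_len=min_len, max_len=max_len)
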