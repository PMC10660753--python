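"""Exact-match read assignment, RPM normalization, and abundance thresholding.

Adapter-trimmed reads are matched to the fragment index as whole strings
only — a read is the molecule, so no substring or mismatch-tolerant matching
is attempted.  Each read increments exactly one fragment row (the one whose
sequence equals the read) or the unmatched tally; a fragment shared by
several transcripts is still a single row, so counting never attributes the
same read to more than one source.

RPM = raw_count * 1e6 / denominator.  The denominator is either the total
number of input reads (``total_input``, the default, the usual convention
for cross-dataset comparison) or the number of tRF-matched reads
(``trf_mapped``).  Downstream analysis applies a minimum-abundance floor
(default 10 RPM); sub-threshold rows are dropped from the analysis set but
kept in exports where they are displayed as 0.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO

from .fragment_index import Exclusivity, FragmentIndex, Placement

__all__ = [
    "ReadSet",
    "ProfileRow",
    "Profile",
    "read_fastq",
    "profile_reads",
    "apply_threshold",
    "write_profile",
    "read_profile",
]

DenominatorPolicy = Literal["total_input", "trf_mapped"]


@dataclass(frozen=True)
class ReadSet:
    """Trimmed reads for one dataset (e.g., one SRR accession)."""

    dataset_id: str
    reads: tuple[str, ...]
    total_input_reads: int

    def __post_init__(self) -> None:
        if not self.dataset_id:
            raise ValueError("dataset_id must be non-empty")
        if self.total_input_reads < len(self.reads):
            raise ValueError(
                "total_input_reads smaller than the number of retained reads"
            )


@dataclass(frozen=True)
class ProfileRow:
    sequence: str
    length: int
    placements: tuple[Placement, ...]
    exclusivity: Exclusivity
    raw_count: int
    rpm: float
    passes_threshold: bool | None = None


@dataclass(frozen=True)
class Profile:
    """Per-dataset fragment abundances (raw counts + RPM)."""

    dataset_id: str
    denominator: int
    denominator_policy: DenominatorPolicy
    rows: tuple[ProfileRow, ...]
    matched_reads: int
    unmatched_reads: int
    total_input_reads: int
    threshold_rpm: float | None = None

    @property
    def analysis_rows(self) -> tuple[ProfileRow, ...]:
        """Rows in the analysis set (all rows until a threshold is applied)."""
        if self.threshold_rpm is None:
            return self.rows
        return tuple(r for r in self.rows if r.passes_threshold)

    def row_for(self, sequence: str) -> ProfileRow | None:
        for r in self.rows:
            if r.sequence == sequence:
                return r
        return None


def read_fastq(path: str | Path, dataset_id: str | None = None) -> ReadSet:
    """Load an adapter-trimmed FASTQ (gzip accepted); qualities are ignored."""
    path = Path(path)
    if dataset_id is None:
        dataset_id = path.name.removesuffix(".gz").removesuffix(".fastq").removesuffix(".fq")
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        reads = tuple(
            str(rec.seq).upper().replace("U", "T")
            for rec in SeqIO.parse(fh, "fastq")
        )
    return ReadSet(dataset_id=dataset_id, reads=reads, total_input_reads=len(reads))


def profile_reads(
    readset: ReadSet,
    index: FragmentIndex,
    denominator_policy: DenominatorPolicy = "total_input",
) -> Profile:
    """Assign reads to fragment space by exact whole-string match and normalize.

    Rows are sorted by (first placement transcript_id, length, sequence) for
    deterministic output.
    """
    if readset.total_input_reads == 0:
        raise ValueError(
            f"dataset {readset.dataset_id}: total_input_reads is 0, "
            "RPM denominator undefined"
        )

    counts: dict[str, int] = {}
    for read in readset.reads:
        counts[read] = counts.get(read, 0) + 1

    matched: dict[str, int] = {}
    unmatched = 0
    for seq, n in counts.items():
        if index.lookup(seq) is not None:
            matched[seq] = n
        else:
            unmatched += n
    n_matched = sum(matched.values())

    if denominator_policy == "total_input":
        denominator = readset.total_input_reads
    elif denominator_policy == "trf_mapped":
        if n_matched == 0:
            raise ValueError(
                f"dataset {readset.dataset_id}: no tRF-matched reads, "
                "trf_mapped denominator undefined"
            )
        denominator = n_matched
    else:
        raise ValueError(f"unknown denominator_policy {denominator_policy!r}")

    rows = []
    for seq, n in matched.items():
        ann = index.lookup(seq)
        assert ann is not None
        rows.append(
            ProfileRow(
                sequence=seq,
                length=len(seq),
                placements=ann.placements,
                exclusivity=ann.exclusivity,
                raw_count=n,
                rpm=n * 1e6 / denominator,
            )
        )
    rows.sort(key=lambda r: (r.placements[0].transcript_id, r.length, r.sequence))

    return Profile(
        dataset_id=readset.dataset_id,
        denominator=denominator,
        denominator_policy=denominator_policy,
        rows=tuple(rows),
        matched_reads=n_matched,
        unmatched_reads=unmatched,
        total_input_reads=readset.total_input_reads,
    )


def apply_threshold(profile: Profile, min_rpm: float = 10.0) -> Profile:
    """Apply the minimum-abundance floor (default 10 RPM, boundary inclusive).

    Rows are retained with a ``passes_threshold`` mark; the analysis set
    afterwards contains only rows with rpm >= min_rpm.
    """
    if min_rpm < 0:
        raise ValueError(f"negative threshold {min_rpm}")
    rows = tuple(
        replace(r, passes_threshold=r.rpm >= min_rpm) for r in profile.rows
    )
    return replace(profile, rows=rows, threshold_rpm=min_rpm)


def _format_placements(placements: Sequence[Placement]) -> str:
    return ";".join(f"{p.transcript_id}:{p.start}-{p.end}" for p in placements)


def _parse_placements(text: str) -> tuple[Placement, ...]:
    out = []
    for item in text.split(";"):
        tid, span = item.rsplit(":", 1)
        s, e = span.split("-")
        out.append(Placement(tid, int(s), int(e)))
    return tuple(out)


def write_profile(profile: Profile, path: str | Path) -> None:
    """Write a profile TSV (rpm with 4 decimals); round-trips via read_profile."""
    with open(path, "w") as fh:
        fh.write(f"# dataset_id={profile.dataset_id}\n")
        fh.write(f"# denominator={profile.denominator}\n")
        fh.write(f"# denominator_policy={profile.denominator_policy}\n")
        fh.write(f"# total_input_reads={profile.total_input_reads}\n")
        fh.write(f"# matched_reads={profile.matched_reads}\n")
        fh.write(f"# unmatched_reads={profile.unmatched_reads}\n")
        thr = "" if profile.threshold_rpm is None else repr(profile.threshold_rpm)
        fh.write(f"# threshold_rpm={thr}\n")
        fh.write(
            "sequence\tlength\tplacements\texclusivity\traw_count\trpm\tpasses_threshold\n"
        )
        for r in profile.rows:
            pt = "" if r.passes_threshold is None else str(r.passes_threshold)
            fh.write(
                f"{r.sequence}\t{r.length}\t{_format_placements(r.placements)}\t"
                f"{r.exclusivity.value}\t{r.raw_count}\t{r.rpm:.4f}\t{pt}\n"
            )


def read_profile(path: str | Path) -> Profile:
    """Read a profile TSV written by :func:`write_profile`."""
    meta: dict[str, str] = {}
    rows: list[ProfileRow] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                key, _, value = line[2:].partition("=")
                meta[key] = value
                continue
            if line.startswith("sequence\t"):
                continue
            seq, length, pl, excl, raw, rpm, pt = line.split("\t")
            rows.append(
                ProfileRow(
                    sequence=seq,
                    length=int(length),
                    placements=_parse_placements(pl),
                    exclusivity=Exclusivity(excl),
                    raw_count=int(raw),
                    rpm=float(rpm),
                    passes_threshold=None if pt == "" else pt == "True",
                )
            )
    return Profile(
        dataset_id=meta["dataset_id"],
        denominator=int(meta["denominator"]),
        denominator_policy=meta["denominator_policy"],  # type: ignore[arg-type]
        rows=tuple(rows),
        matched_reads=int(meta["matched_reads"]),
        unmatched_reads=int(meta["unmatched_reads"]),
        total_input_reads=int(meta["total_input_reads"]),
        threshold_rpm=None if meta["threshold_rpm"] == "" else float(meta["threshold_rpm"]),
    )
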