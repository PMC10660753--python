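"""Mature tRNA transcript space.

Loads annotated tRNA genes (FASTA + tab-delimited annotation), constructs
mature transcripts (intron splicing, post-transcriptional CCA addition, the
His-specific -1 guanosine), collapses genes with end-to-end identical mature
sequences, and partitions transcripts into isodecoder (same amino acid and
anticodon) and isoacceptor (same amino acid) groups.

Two coordinate frames are used throughout the package:

* **mature-linear** — 1-based inclusive positions on the final transcript
  string; a -1 G, when present, is linear position 1.
* **coding-relative** — the first coding nucleotide is 1, the position one
  before it is 0, the CCA tail occupies L+1..L+3 where L is the coding
  length; precursor leader/trailer positions are < 0 / > L.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO

__all__ = [
    "TRNAGene",
    "MatureTranscript",
    "IsoGroup",
    "ReferenceError",
    "load_reference",
    "mature_sequence",
    "collapse_identical",
    "group_transcripts",
    "build_transcript_space",
    "ANNOTATION_COLUMNS",
]

ANNOTATION_COLUMNS = [
    "gene_id",
    "chrom",
    "g_start",
    "g_end",
    "strand",
    "amino_acid",
    "anticodon",
    "intron_start",
    "intron_end",
    "leader_seq",
    "trailer_seq",
]

_DNA = set("ACGTN")

Minus1Policy = Literal["his_only", "never", "all"]


class ReferenceError(ValueError):
    """Raised for malformed or inconsistent reference inputs."""


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class TRNAGene:
    """An annotated genomic tRNA gene.

    ``intron`` is a 1-based inclusive span *within* ``coding_seq``;
    ``leader_seq``/``trailer_seq`` are optional precursor context.
    """

    gene_id: str
    amino_acid: str
    anticodon: str
    chrom: str
    strand: str
    g_start: int
    g_end: int
    coding_seq: str
    intron: tuple[int, int] | None = None
    leader_seq: str | None = None
    trailer_seq: str | None = None

    def __post_init__(self) -> None:
        if self.g_end < self.g_start:
            raise ReferenceError(
                f"gene {self.gene_id}: malformed span {self.g_start}..{self.g_end}"
            )
        if self.strand not in ("+", "-"):
            raise ReferenceError(
                f"gene {self.gene_id}: unknown strand {self.strand!r}"
            )
        if not set(self.coding_seq) <= _DNA:
            bad = sorted(set(self.coding_seq) - _DNA)
            raise ReferenceError(f"gene {self.gene_id}: non-DNA characters {bad}")
        span = self.g_end - self.g_start + 1
        if len(self.coding_seq) != span:
            raise ReferenceError(
                f"gene {self.gene_id}: coding_seq length {len(self.coding_seq)} "
                f"!= genomic span {span}"
            )
        if self.intron is not None:
            i0, i1 = self.intron
            if not (1 <= i0 <= i1 <= len(self.coding_seq)):
                raise ReferenceError(
                    f"gene {self.gene_id}: intron {i0}..{i1} outside coding sequence"
                )

    @property
    def spliced_seq(self) -> str:
        if self.intron is None:
            return self.coding_seq
        i0, i1 = self.intron
        return self.coding_seq[: i0 - 1] + self.coding_seq[i1:]


@dataclass(frozen=True)
class MatureTranscript:
    """A processed mature tRNA sequence (spliced coding + CCA, optional -1 nt).

    ``L`` is the coding length (excludes the -1 nt and the CCA tail);
    ``a_start`` is the mature-linear position of the anticodon's first nt.
    """

    transcript_id: str
    sequence: str
    L: int
    a_start: int
    has_minus1: bool
    amino_acid: str
    anticodon: str
    source_gene_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.sequence.endswith("CCA"):
            raise ReferenceError(
                f"transcript {self.transcript_id}: sequence does not end in CCA"
            )
        expected = self.L + 3 + (1 if self.has_minus1 else 0)
        if len(self.sequence) != expected:
            raise ReferenceError(
                f"transcript {self.transcript_id}: length {len(self.sequence)} != {expected}"
            )
        if self.sequence[self.a_start - 1 : self.a_start + 2] != self.anticodon:
            raise ReferenceError(
                f"transcript {self.transcript_id}: anticodon not at a_start={self.a_start}"
            )

    @property
    def isodecoder_key(self) -> str:
        return f"{self.amino_acid}-{self.anticodon}"

    @property
    def isoacceptor_key(self) -> str:
        return self.amino_acid

    @property
    def shift(self) -> int:
        """Offset between mature-linear and coding-relative coordinates."""
        return 1 if self.has_minus1 else 0


@dataclass(frozen=True)
class IsoGroup:
    key: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ReferenceError(f"iso group {self.key}: empty member set")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def load_reference(fasta_path: str | Path, annotation_path: str | Path) -> list[TRNAGene]:
    """Load tRNA genes from a FASTA plus a tab-delimited annotation table.

    The annotation must contain the columns in :data:`ANNOTATION_COLUMNS`
    (intron/leader/trailer cells may be empty).  Sequences are uppercased
    and U is converted to T.  A gene annotated without a FASTA record is a
    hard error naming the gene.
    """
    with _open_text(fasta_path) as fh:
        seqs = {rec.id: _normalize_seq(str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")}
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing_cols:
        raise ReferenceError(f"annotation missing columns: {missing_cols}")

    genes: list[TRNAGene] = []
    for row in ann.itertuples(index=False):
        gene_id = row.gene_id
        if gene_id not in seqs:
            raise ReferenceError(f"no FASTA sequence for annotated gene {gene_id!r}")
        intron = None
        if row.intron_start != "" or row.intron_end != "":
            if row.intron_start == "" or row.intron_end == "":
                raise ReferenceError(f"gene {gene_id}: half-specified intron span")
            intron = (int(row.intron_start), int(row.intron_end))
        genes.append(
            TRNAGene(
                gene_id=gene_id,
                amino_acid=row.amino_acid,
                anticodon=_normalize_seq(row.anticodon),
                chrom=row.chrom,
                strand=row.strand,
                g_start=int(row.g_start),
                g_end=int(row.g_end),
                coding_seq=seqs[gene_id],
                intron=intron,
                leader_seq=_normalize_seq(row.leader_seq) or None,
                trailer_seq=_normalize_seq(row.trailer_seq) or None,
            )
        )
    return genes


def mature_sequence(gene: TRNAGene, minus1_policy: Minus1Policy = "his_only") -> MatureTranscript:
    """Construct the mature transcript for a gene.

    Splices the intron (if annotated), appends the post-transcriptional CCA,
    and prepends a single -1 G according to ``minus1_policy``: ``his_only``
    (default, only tRNA-His receives it), ``never``, or ``all``.
    """
    spliced = gene.spliced_seq
    pos = spliced.find(gene.anticodon)
    if pos < 0:
        raise ReferenceError(
            f"gene {gene.gene_id}: anticodon {gene.anticodon} not found after splicing"
        )
    a_coding = pos + 1  # 1-based coding position of the anticodon start

    if minus1_policy == "all":
        has_minus1 = True
    elif minus1_policy == "his_only":
        has_minus1 = gene.amino_acid == "His"
    elif minus1_policy == "never":
        has_minus1 = False
    else:
        raise ValueError(f"unknown minus1_policy {minus1_policy!r}")

    seq = ("G" if has_minus1 else "") + spliced + "CCA"
    return MatureTranscript(
        transcript_id=gene.gene_id,
        sequence=seq,
        L=len(spliced),
        a_start=a_coding + (1 if has_minus1 else 0),
        has_minus1=has_minus1,
        amino_acid=gene.amino_acid,
        anticodon=gene.anticodon,
        source_gene_ids=frozenset({gene.gene_id}),
    )


def collapse_identical(transcripts: Iterable[MatureTranscript]) -> list[MatureTranscript]:
    """Merge transcripts with byte-identical sequences.

    The representative transcript_id is the lexicographically smallest source
    gene id; source_gene_ids are unioned.  Identical sequences carrying
    conflicting anticodon/amino-acid annotations are a hard error.
    """
    by_seq: dict[str, list[MatureTranscript]] = {}
    for t in transcripts:
        by_seq.setdefault(t.sequence, []).append(t)

    out: list[MatureTranscript] = []
    for seq, group in by_seq.items():
        anno = {(t.amino_acid, t.anticodon, t.a_start, t.has_minus1) for t in group}
        if len(anno) > 1:
            ids = sorted(i for t in group for i in t.source_gene_ids)
            raise ReferenceError(
                f"identical sequences with conflicting annotations: {ids}"
            )
        sources = frozenset(i for t in group for i in t.source_gene_ids)
        rep = min(sources)
        out.append(replace(group[0], transcript_id=rep, source_gene_ids=sources))
    out.sort(key=lambda t: t.transcript_id)
    return out


def group_transcripts(
    transcripts: Iterable[MatureTranscript],
    level: Literal["isodecoder", "isoacceptor"],
) -> list[IsoGroup]:
    """Partition transcripts into isodecoder or isoacceptor groups, sorted by key."""
    if level not in ("isodecoder", "isoacceptor"):
        raise ValueError(f"unknown grouping level {level!r}")
    groups: dict[str, set[str]] = {}
    for t in transcripts:
        key = t.isodecoder_key if level == "isodecoder" else t.isoacceptor_key
        groups.setdefault(key, set()).add(t.transcript_id)
    return [IsoGroup(key=k, members=frozenset(v)) for k, v in sorted(groups.items())]


def build_transcript_space(
    fasta_path: str | Path,
    annotation_path: str | Path,
    minus1_policy: Minus1Policy = "his_only",
) -> list[MatureTranscript]:
    """Convenience: load genes, build mature transcripts, collapse identicals."""
    genes = load_reference(fasta_path, annotation_path)
    return collapse_identical(mature_sequence(g, minus1_policy) for g in genes)
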