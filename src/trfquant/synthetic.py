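"""Synthetic tRNA references and seeded read simulation.

Generates toy tRNA gene sets with controlled structure — anticodon position,
isodecoder pairs differing at a single internal position, isoacceptor pairs
sharing an amino acid but not an anticodon, a His gene exercising the -1 G —
and simulates small RNA-seq read sets multinomially from a specified
fragment-abundance profile plus a random non-tRNA background.  Background
reads are rejection-sampled against the fragment index so that "unmatched"
is exact by construction.  Everything is deterministic given the seed.

Sequences are generated, not copied from a genome assembly: the presets
reproduce the structural relationships of well-studied human tRNA pairs
(and reuse their printed hg19 spans as plausible annotation metadata), not
their literal nucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import CodingCoords, classify
from .fragment_index import FragmentIndex
from .profiler import Profile
from .reference import ANNOTATION_COLUMNS, MatureTranscript, TRNAGene, ReferenceError

__all__ = [
    "ToyGeneSpec",
    "ToyReferenceSpec",
    "FragmentationProfile",
    "preset",
    "toy_genes",
    "make_toy_reference",
    "draw_reads",
    "simulate_reads",
    "truth_compare",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ToyGeneSpec:
    """One toy tRNA gene: either generated de novo or derived from a base gene.

    ``s`` is the 1-based coding position of the anticodon's first nt;
    ``substitutions`` are (position, base) edits applied to the base gene's
    sequence (positions are 1-based coding positions; landing inside the
    anticodon is an error — anticodon changes go through ``anticodon``).
    """

    gene_id: str
    amino_acid: str
    anticodon: str
    length: int
    s: int
    chrom: str = "chrN"
    g_start: int = 1_000_001
    strand: str = "+"
    base_gene: str | None = None
    substitutions: tuple[tuple[int, str], ...] = ()
    leader_seq: str | None = None
    trailer_seq: str | None = None

    def __post_init__(self) -> None:
        if not (2 <= self.s <= self.length - 2):
            raise ValueError(f"{self.gene_id}: anticodon position s={self.s} out of range")
        if len(self.anticodon) != 3:
            raise ValueError(f"{self.gene_id}: anticodon must be 3 nt")
        for pos, base in self.substitutions:
            if not (1 <= pos <= self.length):
                raise ValueError(f"{self.gene_id}: substitution position {pos} out of range")
            if self.s <= pos <= self.s + 2:
                raise ValueError(
                    f"{self.gene_id}: substitution at {pos} lands inside the anticodon"
                )
            # "?" means "any base different from the base gene's" (cycled A->C->G->T)
            if base not in "ACGT?":
                raise ValueError(f"{self.gene_id}: invalid substitution base {base!r}")


@dataclass(frozen=True)
class ToyReferenceSpec:
    genes: tuple[ToyGeneSpec, ...]
    seed: int = 0


def preset(name: str, seed: int = 0) -> ToyReferenceSpec:
    """Built-in toy references.

    * ``lys-pair`` — two 73-nt LysCTT isodecoders identical except at coding
      position 29 (the classic single-nt isodecoder pair);
    * ``glu-pair`` — two 72-nt Glu transcripts with different anticodons
      (CTC vs TTC) and otherwise near-identical sequences;
    * ``his`` — a His gene whose mature form carries the -1 G.
    """
    if name == "lys-pair":
        genes = (
            ToyGeneSpec(
                gene_id="trna10_LysCTT", amino_acid="Lys", anticodon="CTT",
                length=73, s=34, chrom="chr16", g_start=3_241_501, strand="+",
            ),
            ToyGeneSpec(
                gene_id="trna119_LysCTT", amino_acid="Lys", anticodon="CTT",
                length=73, s=34, chrom="chr1", g_start=145_395_522, strand="-",
                base_gene="trna10_LysCTT", substitutions=((29, "?"),),
            ),
        )
    elif name == "glu-pair":
        genes = (
            ToyGeneSpec(
                gene_id="trna116_GluCTC", amino_acid="Glu", anticodon="CTC",
                length=72, s=34, chrom="chr1", g_start=145_399_233, strand="-",
            ),
            ToyGeneSpec(
                gene_id="trna11_GluTTC", amino_acid="Glu", anticodon="TTC",
                length=72, s=34, chrom="chr15", g_start=26_327_381, strand="-",
                base_gene="trna116_GluCTC", substitutions=((20, "?"), (55, "?")),
            ),
        )
    elif name == "his":
        genes = (
            ToyGeneSpec(
                gene_id="trna1_HisGTG", amino_acid="His", anticodon="GTG",
                length=72, s=34, chrom="chr1", g_start=1_000_001, strand="+",
            ),
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    return ToyReferenceSpec(genes=genes, seed=seed)


def _cycle_base(base: str) -> str:
    order = "ACGT"
    return order[(order.index(base) + 1) % 4]


def _generate_coding(spec: ToyGeneSpec, rng: np.random.Generator) -> str:
    seq = rng.choice(_BASES, size=spec.length)
    seq = "".join(seq)
    return seq[: spec.s - 1] + spec.anticodon + seq[spec.s + 2 :]


def _derive_coding(spec: ToyGeneSpec, base_seq: str) -> str:
    if len(base_seq) != spec.length:
        raise ValueError(f"{spec.gene_id}: base gene length mismatch")
    seq = list(base_seq)
    seq[spec.s - 1 : spec.s + 2] = spec.anticodon
    for pos, base in spec.substitutions:
        if base == "?":
            base = _cycle_base(seq[pos - 1])
        if seq[pos - 1] == base:
            raise ValueError(f"{spec.gene_id}: substitution at {pos} is a no-op")
        seq[pos - 1] = base
    return "".join(seq)


def toy_genes(spec: ToyReferenceSpec, max_attempts: int = 10_000) -> list[TRNAGene]:
    """Materialize a toy reference as :class:`TRNAGene` objects.

    Sequences are drawn from the seed and rejection-sampled so that each
    gene's anticodon occurs *first* at its planted position (the loader
    locates anticodons by first occurrence).
    """
    rng = np.random.default_rng(spec.seed)
    by_id = {g.gene_id: g for g in spec.genes}
    for g in spec.genes:
        if g.base_gene is not None and g.base_gene not in by_id:
            raise ValueError(f"{g.gene_id}: unknown base gene {g.base_gene!r}")

    for _ in range(max_attempts):
        seqs: dict[str, str] = {}
        ok = True
        for g in spec.genes:
            if g.base_gene is None:
                seqs[g.gene_id] = _generate_coding(g, rng)
            else:
                seqs[g.gene_id] = _derive_coding(g, seqs[g.base_gene])
        for g in spec.genes:
            if seqs[g.gene_id].find(g.anticodon) != g.s - 1:
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError("could not generate a reference satisfying the spec")

    genes = []
    for g in spec.genes:
        genes.append(
            TRNAGene(
                gene_id=g.gene_id,
                amino_acid=g.amino_acid,
                anticodon=g.anticodon,
                chrom=g.chrom,
                strand=g.strand,
                g_start=g.g_start,
                g_end=g.g_start + g.length - 1,
                coding_seq=seqs[g.gene_id],
                leader_seq=g.leader_seq,
                trailer_seq=g.trailer_seq,
            )
        )
    return genes


def make_toy_reference(
    spec: ToyReferenceSpec, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the toy reference as FASTA + annotation TSV; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes = toy_genes(spec)
    fasta_path = out_dir / "reference.fasta"
    ann_path = out_dir / "reference.annotation.tsv"
    with open(fasta_path, "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_id}\n{g.coding_seq}\n")
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "g_start": g.g_start,
                "g_end": g.g_end,
                "strand": g.strand,
                "amino_acid": g.amino_acid,
                "anticodon": g.anticodon,
                "intron_start": "",
                "intron_end": "",
                "leader_seq": g.leader_seq or "",
                "trailer_seq": g.trailer_seq or "",
            }
        )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(ann_path, sep="\t", index=False)
    return fasta_path, ann_path


@dataclass(frozen=True)
class FragmentationProfile:
    """Expected molar fractions for simulated fragments plus background.

    ``fractions`` maps (transcript_id, c_start, c_end) — coding-relative
    endpoints — to the fraction of reads drawn for that fragment.  Fractions
    plus ``background_fraction`` must sum to 1.
    """

    fractions: Mapping[tuple[str, int, int], float]
    background_fraction: float = 0.0
    total_reads: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fractions:
            raise ValueError("empty fragmentation profile")
        if any(f < 0 for f in self.fractions.values()) or self.background_fraction < 0:
            raise ValueError("fractions must be non-negative")
        total = sum(self.fractions.values()) + self.background_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")


def _fragment_sequence(
    t: MatureTranscript, c_start: int, c_end: int
) -> str:
    start = c_start + t.shift
    end = c_end + t.shift
    if not (1 <= start <= end <= len(t.sequence)):
        raise ValueError(
            f"fragment {c_start}..{c_end} outside transcript {t.transcript_id}"
        )
    return t.sequence[start - 1 : end]


def draw_reads(
    transcripts: Mapping[str, MatureTranscript],
    profile: FragmentationProfile,
    index: FragmentIndex | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Draw a multinomial read set from the profile; returns (reads, truth).

    The truth table lists, per profiled fragment, its sequence, fraction,
    expected count, and expected RPM under the total-input denominator.
    """
    rng = np.random.default_rng(profile.seed)
    items = sorted(profile.fractions.items())
    seqs = []
    for (tid, c_start, c_end), frac in items:
        if tid not in transcripts:
            raise ValueError(f"profiled fragment on unknown transcript {tid!r}")
        t = transcripts[tid]
        coords = CodingCoords(c_start, c_end, t.a_start - t.shift, t.L)
        classify(coords)  # raises if the span is not a classifiable fragment
        seqs.append(_fragment_sequence(t, c_start, c_end))

    probs = [frac for _, frac in items] + [profile.background_fraction]
    counts = rng.multinomial(profile.total_reads, probs)

    reads: list[str] = []
    for seq, n in zip(seqs, counts[:-1]):
        reads.extend([seq] * int(n))

    n_background = int(counts[-1])
    if n_background:
        if index is None:
            index = FragmentIndex(transcripts.values(), min_len=16, max_len=50)
        for _ in range(n_background):
            while True:
                length = int(rng.integers(27, 42))
                cand = "".join(rng.choice(_BASES, size=length))
                if index.lookup(cand) is None:
                    reads.append(cand)
                    break

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]

    truth = pd.DataFrame(
        {
            "transcript_id": [tid for (tid, _, _), _ in items],
            "c_start": [cs for (_, cs, _), _ in items],
            "c_end": [ce for (_, _, ce), _ in items],
            "sequence": seqs,
            "fraction": [frac for _, frac in items],
            "expected_count": [frac * profile.total_reads for _, frac in items],
            "expected_rpm": [frac * 1e6 for _, frac in items],
        }
    )
    return reads, truth


def simulate_reads(
    transcripts: Mapping[str, MatureTranscript],
    profile: FragmentationProfile,
    fastq_path: str | Path,
    truth_path: str | Path,
    index: FragmentIndex | None = None,
) -> tuple[Path, Path]:
    """Write a simulated FASTQ (constant quality) and its truth TSV."""
    reads, truth = draw_reads(transcripts, profile, index=index)
    fastq_path, truth_path = Path(fastq_path), Path(truth_path)
    with open(fastq_path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i + 1:07d}\n{seq}\n+\n{'I' * len(seq)}\n")
    truth.to_csv(truth_path, sep="\t", index=False, float_format="%.6f")
    return fastq_path, truth_path


def truth_compare(
    profile_out: Profile,
    truth: pd.DataFrame | str | Path,
    index: FragmentIndex | None = None,
) -> pd.DataFrame:
    """Per-fragment z-scores of observed vs expected counts.

    z = (observed - n*p) / sqrt(n*p*(1-p)) under the binomial sampling model,
    aggregating truth rows that share a sequence (the same fragment drawn
    from two transcripts is a single observable row).  z is 0 when expected
    and observed are both 0 (or the variance degenerates with obs == exp).
    """
    if not isinstance(truth, pd.DataFrame):
        truth = pd.read_csv(truth, sep="\t", dtype={"sequence": str})
    if index is not None:
        for seq in truth["sequence"]:
            if index.lookup(seq) is None:
                raise KeyError(f"truth fragment {seq!r} missing from the index")

    agg = truth.groupby("sequence", sort=True)["fraction"].sum().reset_index()
    n = profile_out.total_input_reads
    rows = []
    for seq, p in zip(agg["sequence"], agg["fraction"]):
        row = profile_out.row_for(seq)
        obs = 0 if row is None else row.raw_count
        exp = n * p
        var = n * p * (1.0 - p)
        if var <= 0:
            z = 0.0 if obs == exp else float("inf")
        else:
            z = (obs - exp) / float(np.sqrt(var))
        rows.append({"sequence": seq, "observed": obs, "expected": exp, "z": z})
    return pd.DataFrame(rows)
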