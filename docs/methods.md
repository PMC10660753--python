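# Methods

## Mature tRNA space

A tRNA gene is loaded from a FASTA record plus a tab-delimited annotation
row (gene id, locus, strand, amino acid, anticodon, optional intron span and
precursor leader/trailer). The mature transcript is the spliced coding
sequence with the post-transcriptional `CCA` appended and, under the default
`minus1_policy="his_only"`, a single `G` prepended for tRNA-His — the −1
guanosine added enzymatically to mature His tRNAs. `never` disables the
prepend; `all` prepends a `G` to every transcript as an experimentation
switch (the documented post-transcriptional −1 nucleotide is the His G, so
no genomic −1 lookup is attempted). The loader enforces that the coding
sequence length equals the genomic span, treating a mismatch as an
annotation error rather than an assembly gap.

Genes with byte-identical mature sequences are collapsed into one transcript
(tRNA gene families frequently contain end-to-end identical copies); the
representative id is the lexicographically smallest source gene id, which
makes outputs reproducible under input permutation. Identical sequences with
conflicting anticodon annotations are rejected. The anticodon position is
located as the *first* occurrence of the annotated anticodon in the spliced
sequence; the synthetic generator guarantees by rejection sampling that the
planted occurrence is the first one.

Transcripts partition into isodecoder groups (same amino acid + anticodon)
and isoacceptor groups (same amino acid); the isodecoder partition refines
the isoacceptor partition by construction, and tests assert it.

### Coordinate frames

* **mature-linear**: 1-based positions on the final transcript string; a −1
  G is position 1 when present.
* **coding-relative**: first coding nucleotide = 1, the one-before position
  = 0, the CCA tail = L+1..L+3 where L is the coding length; precursor
  leader/trailer positions are < 0 / > L. Conversion is a shift by 1 iff the
  transcript carries a −1 nucleotide.

The coding-relative frame makes the length arithmetic transparent: a
5′-anchored fragment ending at coding position e has length e (or e+1 under
a −1 start).

## Fragment index

The index contains exactly the distinct substrings of mature transcript
space with lengths in [min_len, max_len] (defaults 16–50 nt, wide enough to
cover all seven structural classes; the vicinity analysis then re-filters to
27–41 nt implicitly through its window). Each entry stores every placement
(transcript, 1-based inclusive span) and an exclusivity level:
`unique_transcript` → `unique_isodecoder` → `unique_isoacceptor` →
`ambiguous`. Because one sequence has one entry, read assignment cannot
double-count across transcripts; per-transcript attribution is only claimed
when exclusivity permits. Desk-scale references make a plain dictionary
index the right data structure; no suffix-automaton machinery is needed, and
an all-substrings brute-force scan serves as the test oracle.

Optional genome flagging marks fragments that occur exactly (either strand)
in a genome FASTA outside the tRNA loci given as a 0-based half-open BED —
candidate false positives whose reads may not be tRNA-derived. Zero flank
tolerance around loci is used (configurable only by editing the BED).
Fragments spanning the non-templated CCA or −1 G are searched as-is and are
typically absent from the genome, hence unflagged. Without a genome the flag
stays `None`, never `False`.

## Read profiling and normalization

Reads are assumed adapter-trimmed, so a read is taken to *be* the molecule:
matching is whole-string exact lookup, and a read that properly contains an
indexed fragment plus extra bases is unmatched. Quality scores are ignored.
Each read increments exactly one row or the unmatched tally
(matched + unmatched = processed reads, asserted on every simulation).

RPM uses one of two denominators: `total_input` (all trimmed reads; the
default, as total-input RPM is the convention for comparisons across
archive datasets) or `trf_mapped` (the matched-read total; degenerate with
zero matched reads, which raises). The abundance floor (default 10 RPM) is
inclusive — "minimum abundance of 10 RPM" reads as rpm ≥ 10 retained.
Sub-threshold rows are removed from the analysis set but kept in exports and
displayed as 0 in cohort matrices.

## Classification and vicinity selection

The classifier is a first-match-wins decision tree on coding-relative
coordinates (precursor leader → trailer → full-length rejection →
CCA-anchored → 5′-anchored → internal). The four 5′-tRH 3′-end positions are
the terminal coding positions {s−1, s, s+1, s+2} — cleavage one nt before
the anticodon, at its start, after its first nt, or after its second nt —
which yields exactly four consecutive half lengths (32–35 nt for s = 33) and
makes 3′-tRHs start at {s..s+3}, i.e., where 5′ halves end. The full-length
molecule (start ∈ {0,1}, end = L+3) is rejected with a distinct signal
before the CCA rules so it cannot be silently labeled a 3′-tRF. Precursor
classes only arise for coordinates in precursor space; the index itself is
built over mature space only, so 5′U-tRFs and tRF-1s are classified when
precursor coordinates are supplied but never produced by indexing.

Vicinity selection keeps profile rows having at least one placement with
c_start ∈ {0, 1} and c_end ∈ [s−w, s+w], default w = 7 (w < 2 is rejected
since it would exclude half endpoints). Selection is placement-level: an
ambiguous fragment qualifies if any placement qualifies and carries all
qualifying placements, so shared rows display against every compatible
source. For s = 34 and no −1 start this admits lengths 27–41 nt; a −1 start
extends the maximum by one.

## Cohort matrices and ratios

The cohort matrix is the union of vicinity-selected rows across datasets,
keyed by (sequence, source label, length, class) with the source label the
sorted "|"-join of qualifying transcript ids. Columns sort by (bioproject,
dataset id). Cells are RPM, 0 when sub-threshold or absent; no scaling or
clustering is applied. `interleave=True` sorts rows by (length, source) so
two source tRNAs alternate line by line for side-by-side comparison. Export
writes a raw matrix and a display copy with values capped (default
1000 RPM, a linear color-scale maximum); both serialize RPM at 4 decimals,
and the raw matrix round-trips at that precision. The abundance ratio of
two fragments is rpm(a)/rpm(b) when both pass the threshold and *undefined*
(`None`) otherwise — undefined is a value, not an error, because
sub-threshold abundances are not considered quantified.

## Synthetic data

The generator emulates the structural situations the analysis must
discriminate: an isodecoder pair differing at a single internal position
(preset `lys-pair`, 73-nt transcripts, difference at coding position 29,
anticodon CTT at 34), an isoacceptor pair with different anticodons and
otherwise near-identical 72-nt sequences (`glu-pair`, CTC vs TTC), and a His
gene exercising the −1 G (`his`). Sequences are drawn from a seeded
generator with the anticodon planted at its position and rejection-sampled
so the planted occurrence is the first; the presets reuse the printed hg19
spans of well-studied human tRNA loci as annotation metadata, but the
nucleotides are generated, not copied from an assembly.

Read sets are drawn multinomially from a fragment-abundance profile
(coding-relative spans → molar fractions) plus a background fraction of
uniform random 27–41-nt sequences rejection-sampled against the index, so
unmatched counts are exact by construction. FASTQ output uses a constant
quality string (quality is ignored downstream); identical (spec, profile,
seed) triples produce byte-identical FASTA/FASTQ/truth files. The truth
table lists each fragment's fraction, expected count, and expected RPM
(fraction × 10⁶ under the total-input denominator); `truth_compare` reports
per-fragment binomial z-scores, aggregating truth rows that share a
sequence, with z defined as 0 when the variance degenerates and observed
equals expected.

What the simulations do **not** emulate: sequencing error, adapter
read-through, quality degradation, base modifications that stall reverse
transcription, ligation biases, or fragments with modified termini. Passing
tests therefore demonstrate the correctness of the counting, normalization
and classification rules under ideal exact-sequence data, not robustness to
real library artifacts — on real data the upstream trimmer and the
exact-match rule absorb those effects by leaving affected reads unmatched.

## Numerical and testing choices

Problem sizes were chosen to keep the full test run in well under a minute
apart from the exhaustive classifier check: toy references of 2–5
transcripts (≤ 1000 nt total mature sequence, where the brute-force index
oracle is cheap), simulations of 3,000–500,000 reads, and 200 seeded
replicates for the RPM-recovery property (observed RPM within 3 binomial
standard deviations of truth in ≥ 99% of fragment × replicate draws). The
classifier is checked exhaustively against an independently coded truth
table for every (c_start, c_end, s, L) with L ≤ 100 in mature space and
with leader/trailer flanks ≤ 3 in precursor space — the decision tree is
piecewise constant in L beyond small offsets, so L ≤ 100 covers all real
tRNAs (L ≈ 70–95). Ratio antisymmetry holds to 1e−9; thresholds compare
with ≥ on exact floats (RPM values at the boundary arise from exact integer
arithmetic, so no epsilon is applied).

## Known limitations

* Exact matching only: a single sequencing error hides a read; abundances
  are therefore conservative on error-prone data.
* The RPM denominator convention of archived datasets is often unstated;
  both conventions are implemented but cross-study comparisons assume
  `total_input`.
* Precursor fragment detection requires leader/trailer sequences in the
  annotation; without them 5′U-tRFs and tRF-1s cannot exist in the index.
* Genome flagging is exact-match with zero flank tolerance; pseudogene
  copies diverged by ≥ 1 nt will not trigger the flag.
* The anticodon must be locatable as its first occurrence in the spliced
  sequence; references where the anticodon string occurs earlier need a
  corrected annotation.
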