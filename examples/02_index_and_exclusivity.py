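"""Exhaustive fragment indexing and the exclusivity boundary.

For two transcripts identical except at one internal position (here 29),
every 5'-anchored fragment shorter than 29 nt occurs in both — its parental
tRNA is undecidable — while fragments of 29 nt or longer cover the
discriminating position and become attributable to a single transcript.
"""

from trfquant import (
    FragmentIndex,
    collapse_identical,
    mature_sequence,
    preset,
    toy_genes,
)

genes = toy_genes(preset("lys-pair", seed=1))
transcripts = collapse_identical(mature_sequence(g) for g in genes)
index = FragmentIndex(transcripts, min_len=16, max_len=50)
print(f"indexed {len(index)} distinct fragment sequences (16-50 nt)")

t10 = next(t for t in transcripts if t.transcript_id == "trna10_LysCTT")
for k in (27, 28, 29, 30):
    ann = index.lookup(t10.sequence[:k])
    print(f"5'-anchored {k}-mer: {len(ann.placements)} placement(s), "
          f"exclusivity {ann.exclusivity.value}")

# The 27- and 28-mers place on both transcripts (unique only at isodecoder
# level); the 29-mer is the first prefix unique to one transcript, because
# it reaches the single differing position.
mutated = "A" + t10.sequence[1:30] if t10.sequence[0] != "A" else "C" + t10.sequence[1:30]
print(f"one-substitution lookup: {index.lookup(mutated)}")
# Matching is exact: a near-miss at Hamming distance 1 returns None.
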