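"""Shared fixtures: toy references, transcript spaces, indexes, profiles."""

from __future__ import annotations

import pytest

from trfquant import (
    FragmentIndex,
    Profile,
    ReadSet,
    collapse_identical,
    mature_sequence,
    preset,
    profile_reads,
    toy_genes,
)


def transcript_space(preset_name: str, seed: int = 1, minus1="his_only"):
    genes = toy_genes(preset(preset_name, seed=seed))
    return {
        t.transcript_id: t
        for t in collapse_identical(mature_sequence(g, minus1) for g in genes)
    }


@pytest.fixture(scope="session")
def lys_pair():
    """Two LysCTT isodecoders identical except at coding position 29."""
    return transcript_space("lys-pair")


@pytest.fixture(scope="session")
def glu_pair():
    """Two Glu transcripts with different anticodons (CTC / TTC)."""
    return transcript_space("glu-pair")


@pytest.fixture(scope="session")
def his_single():
    """One His transcript carrying the post-transcriptional -1 G."""
    return transcript_space("his")


@pytest.fixture(scope="session")
def lys_index(lys_pair):
    return FragmentIndex(lys_pair.values(), min_len=16, max_len=50)


def profile_of(index: FragmentIndex, sequences, dataset_id="DS1") -> Profile:
    """Build a profile with exactly one read per given fragment sequence."""
    reads = tuple(sequences)
    return profile_reads(
        ReadSet(dataset_id=dataset_id, reads=reads, total_input_reads=len(reads)),
        index,
    )
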