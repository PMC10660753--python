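"""Toy reference generation, read simulation, and truth comparison."""

from __future__ import annotations

import numpy as np
import pytest

from trfquant import (
    FragmentIndex,
    FragmentationProfile,
    ReadSet,
    ToyGeneSpec,
    collapse_identical,
    draw_reads,
    make_toy_reference,
    mature_sequence,
    preset,
    profile_reads,
    simulate_reads,
    toy_genes,
    truth_compare,
)


class TestPresets:
    def test_lys_pair_single_nt_isodecoder_difference(self):
        g1, g2 = toy_genes(preset("lys-pair", seed=5))
        assert g1.anticodon == g2.anticodon == "CTT"
        diffs = [i for i, (a, b) in enumerate(zip(g1.coding_seq, g2.coding_seq), 1) if a != b]
        assert diffs == [29]

    def test_glu_pair_same_amino_acid_different_anticodon(self):
        g1, g2 = toy_genes(preset("glu-pair", seed=5))
        assert g1.amino_acid == g2.amino_acid == "Glu"
        assert {g1.anticodon, g2.anticodon} == {"CTC", "TTC"}

    def test_his_mature_has_minus1(self, his_single):
        (t,) = his_single.values()
        assert t.has_minus1 and t.sequence[0] == "G"

    def test_anticodon_planted_first_occurrence(self):
        for name in ("lys-pair", "glu-pair", "his"):
            for g in toy_genes(preset(name, seed=2)):
                t = mature_sequence(g)
                s = t.a_start - t.shift
                assert g.coding_seq.find(g.anticodon) == s - 1

    def test_substitution_in_anticodon_rejected(self):
        with pytest.raises(ValueError, match="anticodon"):
            ToyGeneSpec(
                gene_id="bad", amino_acid="Lys", anticodon="CTT",
                length=73, s=34, substitutions=((35, "A"),),
            )

    def test_seed_determinism_of_reference_files(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        f1, a1 = make_toy_reference(preset("lys-pair", seed=42), d1)
        f2, a2 = make_toy_reference(preset("lys-pair", seed=42), d2)
        assert f1.read_bytes() == f2.read_bytes()
        assert a1.read_bytes() == a2.read_bytes()
        f3, _ = make_toy_reference(preset("lys-pair", seed=43), tmp_path / "c")
        assert f1.read_bytes() != f3.read_bytes()


class TestSimulate:
    def test_single_fragment_fraction_one(self, lys_pair):
        sim = FragmentationProfile(
            fractions={("trna10_LysCTT", 1, 33): 1.0}, total_reads=1000, seed=0
        )
        reads, truth = draw_reads(lys_pair, sim)
        assert len(reads) == 1000 and len(set(reads)) == 1
        assert truth["expected_rpm"].iloc[0] == pytest.approx(1e6)

    def test_background_tally_within_3_sigma(self, lys_pair, lys_index):
        n = 100_000
        sim = FragmentationProfile(
            fractions={("trna10_LysCTT", 1, 33): 0.5},
            background_fraction=0.5,
            total_reads=n,
            seed=77,
        )
        reads, _ = draw_reads(lys_pair, sim, index=lys_index)
        p = profile_reads(ReadSet("S", tuple(reads), len(reads)), lys_index)
        sigma = np.sqrt(n * 0.25)
        assert abs(p.matched_reads - n / 2) < 3 * sigma
        # background reads are rejection-sampled: every one is unmatched
        assert p.matched_reads + p.unmatched_reads == n

    def test_truth_rpm_is_fraction_times_1e6(self, lys_pair):
        sim = FragmentationProfile(
            fractions={("trna10_LysCTT", 1, 33): 0.25, ("trna119_LysCTT", 1, 36): 0.75},
            total_reads=100,
            seed=0,
        )
        _, truth = draw_reads(lys_pair, sim)
        assert sorted(truth["expected_rpm"]) == [250_000.0, 750_000.0]

    def test_fastq_and_truth_seed_determinism(self, lys_pair, tmp_path):
        sim = FragmentationProfile(
            fractions={("trna10_LysCTT", 1, 33): 0.9},
            background_fraction=0.1,
            total_reads=2000,
            seed=9,
        )
        paths = []
        for sub in ("a", "b"):
            d = tmp_path / sub
            d.mkdir()
            paths.append(simulate_reads(lys_pair, sim, d / "r.fastq", d / "t.tsv"))
        (f1, t1), (f2, t2) = paths
        assert f1.read_bytes() == f2.read_bytes()
        assert t1.read_bytes() == t2.read_bytes()

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            FragmentationProfile(fractions={}, total_reads=10, seed=0)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            FragmentationProfile(
                fractions={("t", 1, 30): 0.5}, background_fraction=0.1,
                total_reads=10, seed=0,
            )

    def test_unknown_span_rejected(self, lys_pair):
        sim = FragmentationProfile(
            fractions={("trna10_LysCTT", 1, 500): 1.0}, total_reads=10, seed=0
        )
        with pytest.raises(ValueError, match="outside"):
            draw_reads(lys_pair, sim)

    @pytest.mark.parametrize("name", ["lys-pair", "glu-pair", "his"])
    def test_end_to_end_identifiability_without_background(self, name):
        genes = toy_genes(preset(name, seed=3))
        space = {
            t.transcript_id: t
            for t in collapse_identical(mature_sequence(g) for g in genes)
        }
        idx = FragmentIndex(space.values(), min_len=16, max_len=50)
        tids = sorted(space)
        spans = [(tid, 1, 30 + i) for i, tid in enumerate(tids)] + [(tids[0], 5, 40)]
        sim = FragmentationProfile(
            fractions={span: 1.0 / len(spans) for span in spans},
            total_reads=5000,
            seed=4,
        )
        reads, truth = draw_reads(space, sim, index=idx)
        p = profile_reads(ReadSet("S", tuple(reads), len(reads)), idx)
        assert p.unmatched_reads == 0
        assert {r.sequence for r in p.rows} == set(truth["sequence"])


class TestTruthCompare:
    def test_perfect_match_gives_zero_z(self, lys_pair, lys_index):
        t10 = lys_pair["trna10_LysCTT"].sequence
        sim = FragmentationProfile(
            fractions={("trna10_LysCTT", 1, 33): 1.0}, total_reads=500, seed=0
        )
        reads, truth = draw_reads(lys_pair, sim)
        p = profile_reads(ReadSet("S", tuple(reads), len(reads)), lys_index)
        # fraction 1.0 -> binomial variance degenerates; obs == exp -> z = 0
        z = truth_compare(p, truth, index=lys_index)
        assert (z["z"] == 0).all()

    def test_expected_zero_observed_zero(self, lys_pair, lys_index):
        import pandas as pd

        t10 = lys_pair["trna10_LysCTT"].sequence
        truth = pd.DataFrame(
            {"sequence": [t10[:33]], "fraction": [0.0]}
        )
        p = profile_reads(ReadSet("S", (t10[:36],), 1), lys_index)
        z = truth_compare(p, truth)
        assert z["z"].iloc[0] == 0.0

    def test_missing_from_index_is_error(self, lys_pair, lys_index):
        import pandas as pd

        truth = pd.DataFrame({"sequence": ["A" * 30], "fraction": [0.5]})
        p = profile_reads(
            ReadSet("S", (lys_pair["trna10_LysCTT"].sequence[:33],), 1), lys_index
        )
        with pytest.raises(KeyError, match="missing"):
            truth_compare(p, truth, index=lys_index)

    def test_shared_sequence_fractions_aggregate(self, lys_pair, lys_index):
        # the 27-mer is identical on both transcripts: one observable row
        sim = FragmentationProfile(
            fractions={
                ("trna10_LysCTT", 1, 27): 0.5,
                ("trna119_LysCTT", 1, 27): 0.5,
            },
            total_reads=400,
            seed=1,
        )
        reads, truth = draw_reads(lys_pair, sim)
        p = profile_reads(ReadSet("S", tuple(reads), len(reads)), lys_index)
        z = truth_compare(p, truth, index=lys_index)
        assert len(z) == 1 and z["z"].iloc[0] == 0.0
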