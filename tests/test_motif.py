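import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctdegron.errors import DataError, InvalidArgumentError
from ctdegron.motif import (composition_score, consensus_motif,
                            dipeptide_present, extract_cterm,
                            positional_frequency, reference_motifs,
                            right_anchored_identity, score_degron)
from ctdegron.seqio import AA_ALPHABET, ProteinRecord, SequenceFamily

motifs = st.text(alphabet=AA_ALPHABET, min_size=1, max_size=15)


class TestExtractCterm:
    def test_terminal_helix_k9(self):
        rec = ProteinRecord("adpm", "MKT" * 20 + "RMAAAALVS")
        assert extract_cterm(rec, 9).kmer == "RMAAAALVS"

    def test_full_length_identity(self):
        rec = ProteinRecord("a", "MKTAY")
        assert extract_cterm(rec, 5).kmer == "MKTAY"

    def test_too_short_excluded(self):
        rec = ProteinRecord("a", "MKTAY")
        win = extract_cterm(rec, 10)
        assert win.kmer is None
        assert win.exclusion_reason == "too short"

    def test_x_in_window_excluded(self):
        rec = ProteinRecord("a", "MKTAYAAXAA")
        win = extract_cterm(rec, 5)
        assert win.kmer is None
        assert "X" in win.exclusion_reason


class TestPositionalFrequency:
    def test_identical_sequences_frequency_one(self):
        fam = SequenceFamily([ProteinRecord(f"s{i}", "MKTAYRMSAYGLAAA")
                              for i in range(10)])
        profile = positional_frequency(fam, 10)
        assert profile.n_sequences == 10
        assert (profile.frequencies.max(axis=1) == 1.0).all()

    def test_hand_counted_case(self):
        fam = SequenceFamily([
            ProteinRecord("a", "AAA"),
            ProteinRecord("b", "AAG"),
            ProteinRecord("c", "AAA"),
        ])
        profile = positional_frequency(fam, 3)
        assert profile.frequency(3, "A") == pytest.approx(2 / 3)
        assert profile.frequency(3, "G") == pytest.approx(1 / 3)

    def test_exclusions_all_or_none(self):
        fam = SequenceFamily([
            ProteinRecord("ok", "MKTAYRMSAY"),
            ProteinRecord("short", "MK"),
            ProteinRecord("masked", "MKTAYRMSXY"),
        ])
        profile = positional_frequency(fam, 10)
        assert profile.n_sequences == 1
        assert {i for i, _ in profile.excluded} == {"short", "masked"}
        assert (profile.counts.sum(axis=1) == 1).all()

    def test_zero_includable_errors(self):
        fam = SequenceFamily([ProteinRecord("a", "MK")])
        with pytest.raises(DataError):
            positional_frequency(fam, 10)

    @given(st.lists(st.text(alphabet=AA_ALPHABET, min_size=6, max_size=12),
                    min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_frequencies_sum_to_one(self, seqs):
        fam = SequenceFamily([ProteinRecord(f"q{i}", s)
                              for i, s in enumerate(seqs)])
        profile = positional_frequency(fam, 5)
        np.testing.assert_allclose(profile.frequencies.sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_tsv_percent_format(self, tmp_path):
        fam = SequenceFamily([ProteinRecord("a", "AAA"), ProteinRecord("b", "AAG")])
        profile = positional_frequency(fam, 3)
        p = tmp_path / "profile.tsv"
        profile.to_tsv(p)
        lines = p.read_text().splitlines()
        assert lines[0].split("\t")[1:] == list(AA_ALPHABET)
        assert "50.00" in lines[3]


class TestConsensusMotif:
    def test_degenerate_profile(self):
        fam = SequenceFamily([ProteinRecord(f"s{i}", "MKTAYRMSAYGLAAA")
                              for i in range(5)])
        cons = consensus_motif(positional_frequency(fam, 10))
        assert cons.residues == "RMSAYGLAAA"
        assert all(cons.conserved_flags)
        assert not any(cons.ambiguity_flags)

    def test_exact_half_not_conserved(self):
        fam = SequenceFamily([
            ProteinRecord("a", "AAA"), ProteinRecord("b", "AAA"),
            ProteinRecord("c", "GGG"), ProteinRecord("d", "GGC"),
        ])
        cons = consensus_motif(positional_frequency(fam, 3), threshold=0.5)
        # A is at exactly 0.5 everywhere: strict inequality says not conserved
        assert cons.per_position_frequency[0] == pytest.approx(0.5)
        assert not any(cons.conserved_flags)

    def test_tie_broken_lexicographically_and_flagged(self):
        fam = SequenceFamily([ProteinRecord("a", "GGG"), ProteinRecord("b", "AAA")])
        cons = consensus_motif(positional_frequency(fam, 3))
        assert cons.residues == "AAA"
        assert all(cons.ambiguity_flags)

    def test_single_copy_consensus_is_terminus(self):
        fam = SequenceFamily([ProteinRecord("a", "MKWAYTRMSV")])
        cons = consensus_motif(positional_frequency(fam, 6))
        assert cons.residues == "YTRMSV"

    def test_planted_motif_recovered(self):
        from ctdegron.simulate import FamilySimConfig, evolve_family, simulate_tree

        cfg = FamilySimConfig(n_taxa=60, motif_sub_rate=0.02, seed=42)
        fam = evolve_family(simulate_tree(60, seed=42), cfg)
        cons = consensus_motif(positional_frequency(fam, 10))
        assert cons.residues == cfg.planted_motif


class TestRightAnchoredIdentity:
    def test_euhalothece_seven_of_ten(self):
        assert right_anchored_identity("RMSAYGLAAA", "RMSAYGLREV") == pytest.approx(0.70)

    def test_ssra_two_of_ten(self):
        assert right_anchored_identity("RMSAYGLAAA", "CAANDENYALAA") == pytest.approx(0.20)

    def test_self_identity(self):
        assert right_anchored_identity("RMAAAALVS", "RMAAAALVS") == 1.0

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            right_anchored_identity("", "AA")

    @given(motifs, motifs)
    @settings(max_examples=50, deadline=None)
    def test_symmetric_for_equal_lengths(self, a, b):
        if len(a) == len(b):
            assert right_anchored_identity(a, b) == right_anchored_identity(b, a)
        val = right_anchored_identity(a, b)
        assert 0.0 <= val <= 1.0


class TestCompositionScore:
    def test_adpm_helix(self):
        assert composition_score("RMAAAALVS") == pytest.approx(7 / 9)

    def test_all_in_set(self):
        assert composition_score("AAAA") == 1.0

    def test_none_in_set(self):
        assert composition_score("RRRR") == 0.0


class TestDipeptide:
    def test_overlapping_positions(self):
        present, positions = dipeptide_present("RMSAYGLAAA", "AA")
        assert present and positions == [8, 9]

    def test_absent(self):
        present, positions = dipeptide_present("RMSAYGLREV", "AA")
        assert not present and positions == []

    def test_minimal(self):
        assert dipeptide_present("AA", "AA") == (True, [1])

    def test_bad_dipeptide_length(self):
        with pytest.raises(InvalidArgumentError):
            dipeptide_present("AAA", "AAA")


class TestScoreDegron:
    def test_reference_catalogue_bundled(self):
        refs = reference_motifs()
        assert refs["ADcon"] == "RMSAYGLAAA"
        assert refs["ssrA"] == "CAANDENYALAA"
        assert refs["ADpm_helix"] == "RMAAAALVS"
        assert refs["Euhalothece"] == "RMSAYGLREV"

    def test_score_against_catalogue(self):
        score = score_degron("RMSAYGLAAA")
        assert score.right_anchored_identity["ADcon"] == 1.0
        assert score.right_anchored_identity["Euhalothece"] == pytest.approx(0.70)
        assert score.right_anchored_identity["ssrA"] == pytest.approx(0.20)
        assert 0 <= score.composition_score <= 1


class TestTextLogo:
    def test_logo_shape(self):
        fam = SequenceFamily([ProteinRecord("a", "AAAA"), ProteinRecord("b", "AAAG")])
        logo = positional_frequency(fam, 4).text_logo(max_height=4)
        lines = logo.splitlines()
        assert len(lines) == 6  # 4 stack rows + rule + position indices
        assert all(len(l) == 4 for l in lines)
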