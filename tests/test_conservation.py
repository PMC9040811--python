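"""Alignment, key-residue checks, and motif scanning against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import brute_force_alignment_score, naive_spaced_motif_hits
from qsmine import conservation as C

MAT = C.default_substitution_matrix()


def subscore(a, b):
    return MAT[C.SCORING_ALPHABET.index(a), C.SCORING_ALPHABET.index(b)]


SEQS = st.text(alphabet="ACDG", min_size=1, max_size=8)


class TestAlignGlobal:
    def test_self_alignment_gap_free_with_diagonal_score(self):
        seq = "WHQKLMNPF"
        aln = C.align_global(seq, seq)
        assert aln.aligned_a == aln.aligned_b == seq
        assert aln.score == sum(subscore(c, c) for c in seq)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            C.align_global("", "ACD")

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(SEQS, SEQS)
    def test_score_matches_exhaustive_enumeration(self, a, b):
        got = C.align_global(a, b).score
        expected = brute_force_alignment_score(a, b, subscore, 6.0, 1.0)
        assert got == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(SEQS, SEQS)
    def test_score_symmetry(self, a, b):
        assert C.align_global(a, b).score == C.align_global(b, a).score

    def test_ungapping_rows_recovers_inputs(self):
        aln = C.align_global("MKTWWHAYI", "MKTWHAYI")
        assert aln.aligned_a.replace("-", "") == "MKTWWHAYI"
        assert aln.aligned_b.replace("-", "") == "MKTWHAYI"

    def test_x_scores_zero_against_everything(self):
        assert subscore("X", "W") == 0 and subscore("X", "X") == 0


class TestMapReferencePositions:
    def test_identity_alignment_identity_mapping(self):
        aln = C.align_global("MKTWHAYI", "MKTWHAYI")
        assert C.map_reference_positions(aln, [1, 4, 8]) == {1: 1, 4: 4, 8: 8}

    def test_insertion_in_reference_shifts_candidate_positions(self):
        # reference has a 3-residue insertion relative to the candidate
        ref = "MKTWWWHAYI"
        cand = "MKTHAYI"
        aln = C.align_global(ref, cand)
        mapping = C.map_reference_positions(aln, [2, 8, 10])
        assert mapping[2] == 2
        assert mapping[8] == 5  # shifted by -3 after the insertion
        assert mapping[10] == 7

    def test_position_out_of_range_rejected(self):
        aln = C.align_global("MKT", "MKT")
        with pytest.raises(ValueError):
            C.map_reference_positions(aln, [4])


class TestCheckKeyResidues:
    def test_reference_matches_itself_completely(self, profiles):
        p = profiles["luxi"]
        report = C.check_key_residues("p", p.reference_seq, p)
        assert report.matched_fraction == 1.0
        assert not report.flags

    def test_single_planted_substitution_detected_exactly(self, profiles):
        p = profiles["luxi"]
        seq = list(p.reference_seq)
        seq[22] = "A"  # R23 -> A
        report = C.check_key_residues("p", "".join(seq), p)
        mismatches = [m for m in report.residue_matches if not m.matched]
        assert [(m.position, m.expected, m.observed) for m in mismatches] == [(23, "R", "A")]

    def test_x_never_matches_expected_residue(self, profiles):
        p = profiles["luxi"]
        seq = list(p.reference_seq)
        seq[22] = "X"
        report = C.check_key_residues("p", "".join(seq), p)
        assert not [m for m in report.residue_matches if m.position == 23][0].matched

    def test_truncation_before_last_key_position(self, profiles):
        p = profiles["luxr"]
        report = C.check_key_residues("p", p.reference_seq[:150], p)
        assert "truncated" in report.flags
        tail = [m for m in report.residue_matches if m.position >= 180]
        assert tail and all(m.observed is None and not m.matched for m in tail)

    def test_fraction_monotone_under_added_mutations(self, profiles):
        p = profiles["rpff"]
        seq = list(p.reference_seq)
        prev = 1.0
        for kp in p.key_positions:
            seq[kp.position - 1] = "A" if kp.residue != "A" else "C"
            frac = C.check_key_residues("p", "".join(seq), p).matched_fraction
            assert frac <= prev
            prev = frac
        assert prev == 0.0


class TestSpacedMotif:
    def test_constructed_hit_at_anchor_coordinates(self, motifs):
        motif = motifs["ahld_zinc_hydrolase"]
        seq = "A" * 101 + "HAHADH" + "A" * 71 + "H" + "A" * 21 + "D" + "A" * 30
        scan = C.scan_spaced_motif(seq, motif)
        assert [h.block_starts for h in scan.hits] == [(102, 179, 201)]
        assert not scan.truncated and not scan.motif_absent

    def test_missing_distal_anchor_is_absence(self, motifs):
        motif = motifs["ahld_zinc_hydrolase"]
        seq = "A" * 101 + "HAHADH" + "A" * 71 + "H" + "A" * 60
        scan = C.scan_spaced_motif(seq, motif)
        assert not scan.hits and scan.motif_absent and not scan.truncated

    def test_sequence_ending_inside_spacer_is_truncation(self, motifs):
        motif = motifs["ahld_zinc_hydrolase"]
        seq = "A" * 101 + "HAHADH" + "A" * 10
        scan = C.scan_spaced_motif(seq, motif)
        assert not scan.hits and scan.truncated and not scan.motif_absent

    def test_agrees_with_naive_nested_scan_on_random_sequences(self, motifs):
        motif = motifs["ahld_zinc_hydrolase"]
        rng = np.random.default_rng(17)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(40):
            seq = "".join(alphabet[i] for i in rng.integers(0, 20, size=2000))
            got = [h.block_starts for h in C.scan_spaced_motif(seq, motif).hits]
            expected = naive_spaced_motif_hits(
                seq, motif.blocks, motif.spacers, motif.max_mismatches
            )
            assert got == expected

    def test_invalid_motif_rejected(self):
        with pytest.raises(ValueError):
            C.SpacedMotif("m", ("H",), ((5, 2),), (0, 0))
        with pytest.raises(ValueError):
            C.SpacedMotif("m", (), (), ())


class TestBlockMotif:
    def test_exact_hit_at_planted_offset(self):
        seq = "A" * 50 + "TPGHTPGH" + "A" * 50
        hits = C.scan_block_motif(seq, "TPGHTPGH", 0)
        assert [(h.position, h.distance) for h in hits] == [(51, 0)]

    def test_mismatch_budget(self):
        seq = "A" * 10 + "TPGHSPGH" + "A" * 10
        assert C.scan_block_motif(seq, "TPGHTPGH", 0) == []
        hits = C.scan_block_motif(seq, "TPGHTPGH", 1)
        assert [(h.position, h.distance) for h in hits] == [(11, 1)]

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(23)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        pattern = "TPGH"
        for _ in range(30):
            seq = "".join(alphabet[i] for i in rng.integers(0, 20, size=200))
            got = {(h.position, h.distance) for h in C.scan_block_motif(seq, pattern, 1)}
            expected = set()
            for s in range(len(seq) - len(pattern) + 1):
                d = sum(seq[s + k] != pc for k, pc in enumerate(pattern))
                if d <= 1:
                    expected.add((s + 1, d))
            assert got == expected

    def test_pattern_x_is_wildcard_sequence_x_is_not(self):
        assert C.scan_block_motif("AHW", "AXW", 0)[0].position == 1
        assert C.scan_block_motif("AXW", "AHW", 0) == []


class TestAhldReport:
    def test_reference_is_fully_valid(self, profiles):
        report = C.ahld_conservation_report("p", profiles["ahld"].reference_seq)
        assert not report.flags
        assert report.motif_hits["ahld_zinc_hydrolase"][0].block_starts == (102, 179, 201)
        assert report.motif_hits["ahld_tpgh"][0].position == 176

    def test_broken_distal_anchor_flags_motif_absent(self, profiles):
        seq = profiles["ahld"].reference_seq
        broken = seq[:200] + "A" + seq[201:]
        report = C.ahld_conservation_report("p", broken)
        assert "motif_absent" in report.flags

    def test_truncated_candidate_flags_truncated_not_absent(self, profiles):
        report = C.ahld_conservation_report("p", profiles["ahld"].reference_seq[:130])
        assert "truncated" in report.flags
        assert "motif_absent" not in report.flags
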