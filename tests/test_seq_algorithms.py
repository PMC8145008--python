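import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from viromedeck.seq_algorithms import (
    AA_SCORING,
    NT_SCORING,
    Alignment,
    cds_completeness,
    find_orfs,
    global_align,
    identity_matrix,
    in_silico_pcr,
    pairwise_identity,
    reverse_complement,
)

from _oracles import enumerate_align_score, naive_orf_scan, recursive_align_score


def random_seq(rng, lo, hi):
    return "".join(rng.choice(list("ACGT"), rng.integers(lo, hi + 1)))


class TestGlobalAlign:
    def test_identical_sequences_score_length_times_match(self):
        aln = global_align("ACGTACGT", "ACGTACGT")
        assert aln.score == 8 * NT_SCORING.match
        assert "-" not in aln.aligned_a + aln.aligned_b

    def test_length_difference_forces_a_gap(self):
        aln = global_align("ACGT", "AGT")
        assert (aln.aligned_a + aln.aligned_b).count("-") == 1

    def test_score_equals_full_enumeration_for_short_pairs(self, rng):
        sc = NT_SCORING
        for _ in range(30):
            a, b = random_seq(rng, 1, 5), random_seq(rng, 1, 5)
            expected = enumerate_align_score(a, b, sc.match, sc.mismatch, sc.gap_open, sc.gap_extend)
            assert global_align(a, b).score == pytest.approx(expected)

    def test_score_equals_recursive_oracle_up_to_length_eight(self, rng):
        sc = NT_SCORING
        for _ in range(200):
            a, b = random_seq(rng, 1, 8), random_seq(rng, 1, 8)
            expected = recursive_align_score(a, b, sc.match, sc.mismatch, sc.gap_open, sc.gap_extend)
            assert global_align(a, b).score == pytest.approx(expected)

    def test_score_matches_reference_aligner(self, rng):
        from Bio import Align

        sc = NT_SCORING
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = sc.match
        aligner.mismatch_score = sc.mismatch
        aligner.open_gap_score = -(sc.gap_open + sc.gap_extend)
        aligner.extend_gap_score = -sc.gap_extend
        for _ in range(40):
            a, b = random_seq(rng, 5, 40), random_seq(rng, 5, 40)
            assert global_align(a, b).score == pytest.approx(aligner.score(a, b))

    def test_protein_level_uses_substitution_matrix(self):
        aln = global_align("MKV", "MKV", AA_SCORING)
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        assert aln.score == blosum["M", "M"] + blosum["K", "K"] + blosum["V", "V"]

    def test_illegal_character_rejected(self):
        with pytest.raises(ValueError, match="illegal"):
            global_align("ACGJ", "ACG")


class TestPairwiseIdentity:
    def test_identical_is_hundred(self):
        assert pairwise_identity(global_align("ACGT", "ACGT")) == 100.0

    def test_one_mismatch_in_four(self):
        assert pairwise_identity(Alignment("ACGT", "ACGA", 0)) == 75.0

    def test_terminal_gaps_excluded_internal_counted(self):
        aln = Alignment("AACGT", "--CGT", 0)
        assert pairwise_identity(aln, "sdt") == 100.0  # overhang excluded
        aln = Alignment("AC-GT", "ACCGT", 0)
        assert pairwise_identity(aln, "sdt") == pytest.approx(80.0)  # internal gap mismatch
        assert pairwise_identity(aln, "exclude_gaps") == 100.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        a=st.text(alphabet="ACGT", min_size=1, max_size=12),
        b=st.text(alphabet="ACGT", min_size=1, max_size=12),
    )
    def test_identity_is_symmetric(self, a, b):
        ab = pairwise_identity(global_align(a, b))
        ba = pairwise_identity(global_align(b, a))
        assert ab == pytest.approx(ba)

    def test_gapped_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Alignment("ACGT", "ACG", 0)


class TestIdentityMatrix:
    def test_identical_pair_is_all_hundred(self):
        mat = identity_matrix({"a": "ACGTAC", "b": "ACGTAC"})
        assert (mat.values == 100.0).all()

    def test_symmetric_with_unit_diagonal(self, rng):
        seqs = {f"s{i}": random_seq(rng, 20, 40) for i in range(4)}
        mat = identity_matrix(seqs)
        np.testing.assert_allclose(mat.values, mat.values.T)
        np.testing.assert_allclose(np.diag(mat.values), 100.0)

    def test_entries_match_individual_calls(self, rng):
        seqs = {f"s{i}": random_seq(rng, 15, 30) for i in range(4)}
        mat = identity_matrix(seqs)
        names = list(seqs)
        for i, ni in enumerate(names):
            for nj in names[i + 1 :]:
                expected = pairwise_identity(global_align(seqs[ni], seqs[nj]))
                assert mat.loc[ni, nj] == pytest.approx(expected)


class TestFindOrfs:
    def test_exactly_minimum_length_is_excluded(self):
        # ATG + 98 codons + stop = 300 nt exactly: the strict cutoff drops it
        orf_300 = "ATG" + "GCT" * 98 + "TAA"
        assert find_orfs(orf_300, 300, both_strands=False) == []
        orf_303 = "ATG" + "GCT" * 99 + "TAA"
        found = find_orfs(orf_303, 300, both_strands=False)
        assert len(found) == 1 and found[0].length_nt == 303

    def test_no_start_codon_means_no_orf(self):
        assert find_orfs("GCT" * 200, 0) == []

    def test_nested_starts_report_only_longest(self):
        seq = "ATGAAAATGAAATAA"
        found = find_orfs(seq, 0, both_strands=False)
        assert len(found) == 1
        assert found[0].start == 1 and found[0].end == 15

    def test_protein_translation_and_invariants(self):
        seq = "ATGGCTGAATAA"  # M A E stop
        orf = find_orfs(seq, 0, both_strands=False)[0]
        assert orf.protein == "MAE"
        assert orf.length_nt % 3 == 0
        assert len(orf.protein) == orf.length_nt // 3 - 1

    def test_matches_naive_six_frame_scan(self, rng):
        for _ in range(5):
            seq = random_seq(rng, 1500, 2000)
            found = {(o.start, o.end, o.strand) for o in find_orfs(seq, 150)}
            assert found == naive_orf_scan(seq, 150)

    def test_invariant_to_noncoding_suffix(self, rng):
        seq = "ATG" + "GCT" * 120 + "TAA"
        plus = [o for o in find_orfs(seq, 300) if o.strand == "+"]
        extended = seq + "CCCCCC"  # no ATG, no in-frame continuation
        plus_ext = [o for o in find_orfs(extended, 300) if o.strand == "+"]
        assert [(o.start, o.end) for o in plus] == [(o.start, o.end) for o in plus_ext]


class TestCdsCompleteness:
    def test_near_full_above_ninety(self):
        fraction, near_full = cds_completeness(95, 100)
        assert fraction == 0.95 and near_full

    def test_exactly_ninety_percent_is_not_near_full(self):
        fraction, near_full = cds_completeness(90, 100)
        assert fraction == 0.9 and not near_full

    def test_complete_cds(self):
        assert cds_completeness(100, 100) == (1.0, True)

    def test_overlong_recovery_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            fraction, near_full = cds_completeness(110, 100)
        assert fraction == 1.0 and near_full

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            cds_completeness(0, 100)


class TestInSilicoPcr:
    FWD = "GCTGGCTTTTCAGACGGCTCTA"
    REV = "TGGATTACCGCTAGGCATCCCA"

    def template(self, rng, fwd_at=8007, rev_at=9134, length=9500):
        bases = rng.choice(list("ACGT"), length)
        bases[fwd_at - 1 : fwd_at - 1 + len(self.FWD)] = list(self.FWD)
        rc = reverse_complement(self.REV)
        bases[rev_at - len(rc) : rev_at] = list(rc)
        return "".join(bases)

    def test_published_coordinates_give_1127_region(self, rng):
        amps = in_silico_pcr(self.template(rng), self.FWD, self.REV)
        assert len(amps) == 1
        amp = amps[0]
        assert (amp.fwd_start, amp.rev_start) == (8007, 9134)
        assert amp.region_length == 1127
        assert amp.product_length == 1128

    def test_degenerate_primer_matches_both_bases(self):
        for base in "AG":
            template = "CCCCCCCCCC" + base + "CCCCCCCCC" + "GGGGGGGGGGGG"
            fwd = "CCCCCCCCCCRCCCCCCCC"  # R = A/G
            amps = in_silico_pcr(template, fwd, "CCCCCCCCCCCC")
            assert len(amps) == 1

    def test_template_without_sites_yields_empty_list(self, rng):
        amps = in_silico_pcr("".join(rng.choice(list("ACGT"), 2000)), self.FWD, self.REV)
        assert amps == []

    def test_reverse_complemented_template_mirrors_coordinates(self, rng):
        template = self.template(rng)
        amps = in_silico_pcr(template, self.FWD, self.REV)[0]
        mirrored = in_silico_pcr(reverse_complement(template), self.REV, self.FWD)[0]
        n = len(template)
        assert mirrored.fwd_start == n - amps.rev_start + 1
        assert mirrored.rev_start == n - amps.fwd_start + 1
        assert mirrored.region_length == amps.region_length

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError, match="shorter than 10"):
            in_silico_pcr("ACGT" * 100, "ACGTACG", self.REV)
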