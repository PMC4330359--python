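"""Composite motif words: revcomp, annealing, scanning, mutagenesis, PFMs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import oracle_revcomp, oracle_scan
from soxpax.motifs import (
    AnnealMismatch,
    CompositeMotif,
    IUPACWord,
    MotifError,
    PositionFrequencyMatrix,
    SwitchPositionSet,
    anneal_check,
    build_flipped_composite,
    enumerate_spacer_variants,
    enumerate_switch_mutants,
    high_ic_deviations,
    information_content,
    match_word,
    parse_pfm,
    reverse_complement,
    scan_composite,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestReverseComplement:
    def test_palindrome(self):
        assert reverse_complement("ACGT") == "ACGT"

    def test_dc5_oligos_are_reverse_complements(self, dc5_forward, dc5_reverse):
        assert reverse_complement(dc5_forward) == dc5_reverse

    def test_iupac_awareness(self):
        assert reverse_complement("RYN") == "NRY"

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(dna)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_matches_independent_table(self):
        rng = np.random.default_rng(1)
        letters = list("ACGTRYSWKMBDHVN")
        for _ in range(100):
            seq = "".join(rng.choice(letters, size=rng.integers(1, 30)))
            assert reverse_complement(seq) == oracle_revcomp(seq)

    def test_invalid_letter(self):
        with pytest.raises(MotifError):
            reverse_complement("ACGX")


class TestAnnealCheck:
    def test_dc5_duplex_is_31_bp(self, dc5_forward, dc5_reverse):
        assert anneal_check(dc5_forward, dc5_reverse) == 31

    def test_perfect_two_mer(self):
        assert anneal_check("AC", "GT") == 2

    def test_mismatch_reports_position(self):
        with pytest.raises(AnnealMismatch) as exc:
            anneal_check("AC", "GG")
        assert exc.value.position == 1

    def test_length_mismatch_not_silent(self):
        with pytest.raises(AnnealMismatch):
            anneal_check("ACGT", "ACG")


class TestMatchWord:
    def test_n_matches_anything(self):
        for base in "ACGT":
            assert match_word(IUPACWord("N"), base, 0)

    def test_dc5_sox_halfsite_position(self, dc5_forward):
        word = IUPACWord("CATTGT")
        assert match_word(word, dc5_forward, 2)
        assert not match_word(word, dc5_forward, 3)

    def test_out_of_bounds(self):
        with pytest.raises(MotifError):
            match_word(IUPACWord("ACGT"), "ACG", 0)

    def test_softmask_default_and_respect(self):
        assert match_word(IUPACWord("ACGT"), "acgt", 0)
        assert not match_word(IUPACWord("ACGT"), "acgt", 0, respect_mask=True)


class TestScanComposite:
    dc5_motif = CompositeMotif(IUPACWord("CATTGT"), IUPACWord("TGTTGC"), gap=0)

    def test_sequence_shorter_than_motif(self):
        assert scan_composite(self.dc5_motif, "CATTG") == []

    def test_single_hit_on_dc5(self, dc5_forward):
        hits = scan_composite(self.dc5_motif, dc5_forward, both_strands=True)
        assert len(hits) == 1
        assert hits[0].offset == 2 and hits[0].strand == "+"
        assert hits[0].matched_span == (2, 14)

    def test_minus_strand_hit_on_reverse_oligo(self, dc5_reverse):
        hits = scan_composite(self.dc5_motif, dc5_reverse, both_strands=True)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].matched_span == (17, 29)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        seq=dna,
        sox=st.text("ACGTRYN", min_size=1, max_size=4),
        pax=st.text("ACGTRYN", min_size=1, max_size=4),
        gap=st.integers(0, 3),
        flipped=st.booleans(),
    )
    def test_agrees_with_exhaustive_oracle(self, seq, sox, pax, gap, flipped):
        motif = CompositeMotif(
            IUPACWord(sox), IUPACWord(pax), gap,
            "flipped" if flipped else "forward",
        )
        got = [
            (h.matched_span[0], h.matched_span[1], h.strand)
            for h in scan_composite(motif, seq, both_strands=True)
        ]
        assert got == oracle_scan(sox, pax, gap, seq, flipped=flipped)

    def test_strand_symmetry(self):
        """Hits on revcomp(seq) are the mirrored hits with strands swapped."""
        rng = np.random.default_rng(9)
        motif = CompositeMotif(IUPACWord("CWT"), IUPACWord("GYT"), gap=1)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            fwd = scan_composite(motif, seq, both_strands=True)
            rev = scan_composite(motif, reverse_complement(seq), both_strands=True)
            n = len(seq)
            mirrored = sorted(
                (n - h.matched_span[1], n - h.matched_span[0],
                 "+" if h.strand == "-" else "-")
                for h in rev
            )
            assert sorted(
                (h.matched_span[0], h.matched_span[1], h.strand) for h in fwd
            ) == mirrored


class TestFlippedComposite:
    motif = CompositeMotif(IUPACWord("CATTGT"), IUPACWord("TCACGC"), gap=1)

    def test_double_flip_is_identity(self):
        assert build_flipped_composite(build_flipped_composite(self.motif)) == self.motif

    def test_flipped_scan_finds_reverse_complement_pax(self):
        seq = "CATTGT" + "A" + reverse_complement("TCACGC") + "AAAA"
        flipped = build_flipped_composite(self.motif)
        hits = [h for h in scan_composite(flipped, seq) if h.strand == "+"]
        assert len(hits) == 1 and hits[0].matched_span == (0, 13)

    def test_flipped_scan_misses_unflipped_site(self):
        # pax word is non-palindromic, so the native site is invisible flipped
        seq = "CATTGT" + "A" + "TCACGC" + "AAAA"
        assert scan_composite(build_flipped_composite(self.motif), seq) == []
        assert len(scan_composite(self.motif, seq)) == 1


class TestSpacerVariants:
    template = "GGCATTGTAATGTTGCGG"  # sox [2,8), spacer AA, pax [10,16)
    sox_span, pax_span = (2, 8), (10, 16)

    def test_zero_delta_is_identity(self):
        out = enumerate_spacer_variants(self.template, self.sox_span, self.pax_span, [0])
        assert out == [(0, self.template)]

    def test_seven_spacer_series_lengths(self):
        """The studied series: -2, -1, +1..+5, lengths L-2 .. L+5."""
        deltas = [-2, -1, 1, 2, 3, 4, 5]
        out = enumerate_spacer_variants(
            self.template, self.sox_span, self.pax_span, deltas, insert_bases="CTGCA"
        )
        assert [d for d, _ in out] == deltas
        assert [len(s) for _, s in out] == [len(self.template) + d for d in deltas]

    def test_half_sites_preserved_verbatim(self):
        deltas = [-2, -1, 0, 1, 2, 3, 4, 5]
        for delta, seq in enumerate_spacer_variants(
            self.template, self.sox_span, self.pax_span, deltas, insert_bases="CTGCA"
        ):
            s0, s1 = self.sox_span
            p0, p1 = self.pax_span
            assert seq[s0:s1] == self.template[s0:s1]
            assert seq[p0 + delta : p1 + delta] == self.template[p0:p1]

    def test_deletion_into_half_site_refused(self):
        with pytest.raises(MotifError):
            enumerate_spacer_variants(self.template, self.sox_span, self.pax_span, [-3])

    def test_positive_delta_requires_insert_bases(self):
        with pytest.raises(MotifError):
            enumerate_spacer_variants(self.template, self.sox_span, self.pax_span, [2])


class TestSwitchMutants:
    wild = "AACAACAATGAA"  # 12-mer toy half-site
    consensus = "AATAACAGCGTA"  # differs at 1-based 3, 8, 9, 11

    def test_combinatorics_up_to_order_three(self):
        positions = SwitchPositionSet(frozenset({3, 8, 9, 11}))
        variants = enumerate_switch_mutants(self.wild, self.consensus, positions, 3)
        assert len(variants) == 4 + 6 + 4

    def test_single_mutants(self):
        positions = SwitchPositionSet(frozenset({3, 8, 9, 11}))
        singles = enumerate_switch_mutants(self.wild, self.consensus, positions, 1)
        assert sorted(v.label for v in singles) == ["C9", "G8", "T11", "T3"]

    def test_subset_hamming_distances(self):
        positions = SwitchPositionSet(frozenset({8, 9}))
        (v,) = [
            v
            for v in enumerate_switch_mutants(self.wild, self.consensus, positions, 2)
            if v.positions == (8, 9)
        ]
        assert v.label == "G8C9"
        ham_wild = sum(a != b for a, b in zip(v.sequence, self.wild))
        ham_cons = sum(a != b for a, b in zip(v.sequence, self.consensus))
        assert ham_wild == 2
        assert ham_cons == sum(a != b for a, b in zip(self.wild, self.consensus)) - 2

    def test_agreeing_position_warns_but_emits(self):
        positions = SwitchPositionSet(frozenset({1}))  # wild==consensus at 1
        with pytest.warns(UserWarning):
            variants = enumerate_switch_mutants(self.wild, self.consensus, positions, 1)
        assert len(variants) == 1


JASPAR_TOY = """>MA0069.1 Pax6
A [ 3 0 ]
C [ 1 0 ]
G [ 0 0 ]
T [ 0 4 ]
"""


class TestPFM:
    def test_parse_jaspar_header_and_counts(self):
        pfm = parse_pfm(JASPAR_TOY)
        assert pfm.motif_id == "MA0069.1"
        assert len(pfm) == 2
        assert pfm.consensus() == "AT"

    def test_single_column(self):
        pfm = parse_pfm(">toy\nA [ 4 ]\nC [ 0 ]\nG [ 0 ]\nT [ 0 ]\n")
        assert len(pfm) == 1

    def test_missing_row_is_parse_error(self):
        with pytest.raises(MotifError):
            parse_pfm(">bad\nA [ 1 ]\nC [ 1 ]\nG [ 1 ]\n")

    def test_ragged_rows_rejected(self):
        with pytest.raises(MotifError):
            parse_pfm(">bad\nA [ 1 2 ]\nC [ 1 ]\nG [ 1 2 ]\nT [ 1 2 ]\n")

    def test_negative_counts_rejected(self):
        with pytest.raises(MotifError):
            PositionFrequencyMatrix(np.array([[-1.0], [1.0], [1.0], [1.0]]), "bad")


class TestInformationContent:
    def _pfm_from_columns(self, cols):
        return PositionFrequencyMatrix(np.array(cols, dtype=float).T, "toy")

    def test_uniform_column_zero_bits(self):
        pfm = self._pfm_from_columns([[1, 1, 1, 1]])
        assert information_content(pfm, pseudocount=0)[0] == pytest.approx(0.0)

    def test_deterministic_column_two_bits(self):
        pfm = self._pfm_from_columns([[100, 0, 0, 0]])
        assert information_content(pfm, pseudocount=0)[0] == pytest.approx(2.0)

    def test_half_bit_column(self):
        pfm = self._pfm_from_columns([[2, 1, 1, 0]])
        assert information_content(pfm, pseudocount=0)[0] == pytest.approx(0.5)

    def test_bounded_and_shrinks_with_pseudocount(self):
        rng = np.random.default_rng(4)
        cols = rng.integers(0, 50, size=(10, 4)) + np.eye(4)[rng.integers(0, 4, 10)]
        pfm = self._pfm_from_columns(cols)
        prev = information_content(pfm, pseudocount=0)
        assert np.all(prev >= 0) and np.all(prev <= 2)
        for pc in (0.25, 1.0, 10.0, 100.0):
            cur = information_content(pfm, pseudocount=pc)
            assert np.all(cur <= prev + 1e-12)
            prev = cur


class TestHighICDeviations:
    def _toy_14col(self):
        """14-column toy PFM: informative consensus T/G/C/T at 1-based
        positions 3, 8, 9, 11; uninformative (uniform) elsewhere."""
        cols = []
        informative = {3: "T", 8: "G", 9: "C", 11: "T"}
        for pos in range(1, 15):
            if pos in informative:
                col = [0, 0, 0, 0]
                col["ACGT".index(informative[pos])] = 100
            else:
                col = [25, 25, 25, 25]
            cols.append(col)
        return PositionFrequencyMatrix(np.array(cols, dtype=float).T, "toy14")

    def test_recovers_switch_positions(self):
        pfm = self._toy_14col()
        halfsite = "AAAAAAAAAAAAAA"  # deviates at every informative position
        assert high_ic_deviations(pfm, halfsite, ic_threshold=1.0, pseudocount=0) == {
            3, 8, 9, 11
        }

    def test_consensus_halfsite_gives_empty_set_with_warning(self):
        pfm = self._toy_14col()
        with pytest.warns(UserWarning):
            out = high_ic_deviations(pfm, pfm.consensus(), 1.0, pseudocount=0)
        assert out == frozenset()

    def test_single_position(self):
        pfm = PositionFrequencyMatrix(np.array([[100.0], [0], [0], [0]]), "p1")
        assert high_ic_deviations(pfm, "C", 1.0, pseudocount=0) == {1}

    def test_length_mismatch(self):
        pfm = PositionFrequencyMatrix(np.array([[100.0], [0], [0], [0]]), "p1")
        with pytest.raises(MotifError):
            high_ic_deviations(pfm, "CC", 1.0)
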