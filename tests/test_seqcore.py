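"""Alignment, distance, consensus and translation primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ltrtrace as lt
from ltrtrace.errors import (
    AlignmentShapeError,
    DegenerateSequenceError,
    SaturationError,
)
from ltrtrace.seqcore import (
    AlignParams,
    count_site_patterns,
    k2p_from_counts,
    translate,
)
from oracles import brute_global_score, k2p_by_counting, sw_affine_score

dna = st.text(alphabet="ACGT", min_size=1, max_size=12)


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = lt.global_align("ACGT", "ACGT")
        assert aln.identity == 1.0
        assert aln.aligned_columns == 4

    def test_single_gap_example(self):
        aln = lt.global_align("ACGT", "AGT", AlignParams(1, -1, -2, -2))
        assert aln.score == 1
        assert (aln.gapped_a, aln.gapped_b) == ("ACGT", "A-GT")

    def test_all_mismatch(self):
        aln = lt.global_align("AAAA", "TTTT", AlignParams(1, -1, -2, -2))
        assert aln.identity == 0.0

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(1, 6)))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(1, 6)))
            got = lt.global_align(a, b, AlignParams(1, -1, -3, -1)).score
            assert got == brute_global_score(a, b, 1, -1, -3, -1)

    @settings(max_examples=60, derandomize=True)
    @given(dna, dna)
    def test_score_symmetric(self, a, b):
        p = AlignParams(2, -1, -4, -1)
        assert lt.global_align(a, b, p).score == lt.global_align(b, a, p).score

    def test_ambiguity_never_matches(self):
        aln = lt.global_align("ANNA", "ANNA", AlignParams(1, -1, -5, -5))
        assert aln.identity == 0.5  # the two N columns are not identities

    def test_empty_raises(self):
        with pytest.raises(DegenerateSequenceError):
            lt.global_align("", "ACGT")


class TestLocalProtein:
    def test_identical_full_span(self):
        q = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSG"
        hit = lt.local_align_protein(q, q)
        assert hit.query_span == (0, len(q))
        assert hit.target_span == (0, len(q))
        assert hit.pair.identity == 1.0

    def test_embedded_query_span(self):
        q = "MKTAYIAKQR"
        t = "GGGWWW" + q + "CCCPPP"
        hit = lt.local_align_protein(q, t)
        assert hit.target_span == (6, 6 + len(q))

    def test_matches_gotoh_oracle(self):
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load("BLOSUM62")
        rng = np.random.default_rng(3)
        aas = "ARNDCQEGHILKMFPSTWYV"
        for _ in range(8):
            q = "".join(aas[i] for i in rng.integers(0, 20, 30))
            t = "".join(aas[i] for i in rng.integers(0, 20, 300))
            assert lt.local_align_protein(q, t).score == sw_affine_score(q, t, m, -11, -1)

    def test_empty_raises(self):
        with pytest.raises(DegenerateSequenceError):
            lt.local_align_protein("", "MKT")


class TestK2P:
    def test_identical_is_zero(self):
        d = lt.k2p_distance(lt.global_align("ACGTACGT", "ACGTACGT"))
        assert d.P == d.Q == 0.0
        assert d.k2p == 0.0 and d.jc == 0.0

    def test_hand_evaluated_example(self):
        # 200 sites: 20 transitions, 10 transversions
        d = k2p_from_counts(20, 10, 200)
        assert d.P == 0.10 and d.Q == 0.05
        assert d.k2p == pytest.approx(-0.5 * math.log(0.75) - 0.25 * math.log(0.9), abs=1e-12)
        assert d.k2p == pytest.approx(0.1702, abs=5e-5)

    def test_jc_hand_example(self):
        assert lt.jc_distance(0.06) == pytest.approx(-0.75 * math.log(0.92), abs=1e-12)
        assert lt.jc_distance(0.06) == pytest.approx(0.0625, abs=5e-5)

    def test_gap_and_ambiguity_columns_excluded(self):
        ts, tv, sites = count_site_patterns("AC-GNT", "AT-GAT")
        assert sites == 4  # gap and N columns dropped
        assert (ts, tv) == (1, 0)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_from_counts(60, 0, 100)  # 1-2P-Q <= 0

    def test_no_sites_raises(self):
        with pytest.raises(DegenerateSequenceError):
            lt.k2p_distance(lt.AlignedPair("NNN", "NNN", 0, 0, 0))

    @pytest.mark.parametrize("k", [1, 5, 10, 20, 37])
    def test_k2p_equals_jc_at_equal_substitution_rates(self, k):
        # transitions : transversions = 1 : 2 (P = p/3, Q = 2p/3) collapses
        # the K2P form onto Jukes-Cantor exactly
        d = k2p_from_counts(k, 2 * k, 300)
        assert d.k2p == pytest.approx(d.jc, abs=1e-12)

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(5)
        bases = "ACGT-"
        for _ in range(25)       :
            n = int(rng.integers(50, 200))
            a = "".join(bases[i] for i in rng.integers(0, 5, n))
            b = "".join(bases[min(i, 4)] for i in rng.integers(0, 6, n))
            pair = lt.AlignedPair(a, b, 0, 0, 0)
            try:
                d = lt.k2p_distance(pair)
            except (SaturationError, DegenerateSequenceError):
                continue
            P, Q, sites, k, jc = k2p_by_counting(a, b)
            assert (d.P, d.Q, d.sites) == (P, Q, sites)
            assert d.k2p == pytest.approx(k, abs=1e-12)
            assert d.jc == pytest.approx(jc, abs=1e-12)


class TestConsensus:
    def test_identical_sequences(self):
        c = lt.majority_consensus(["ACGT"] * 5)
        assert c.consensus == "ACGT"

    def test_forced_majority(self):
        c = lt.majority_consensus(["A", "A", "C"])
        assert c.consensus == "A"
        assert c.column_support == [pytest.approx(2 / 3)]

    def test_tie_broken_alphabetically(self):
        c = lt.majority_consensus(["AC", "AC", "CA", "CA"])
        # both columns tie A/C at 0.5 -> alphabetical winner 'A'... column 1:
        # {A:2, C:2} -> A; column 2: {C:2, A:2} -> A
        assert c.consensus == "AA"
        assert c.column_support == [0.5, 0.5]

    def test_below_cutoff_gives_n(self):
        c = lt.majority_consensus(["A", "C", "G", "T"], cutoff=0.5)
        assert c.consensus == "N"

    def test_gap_majority_column_dropped(self):
        c = lt.majority_consensus(["A-G", "A-G", "ACG"])
        assert c.consensus == "AG"

    def test_idempotent(self):
        seqs = ["ACGTAC", "ACGTTC", "ACCTAC", "TCGTAC"]
        cons = lt.majority_consensus(seqs).consensus
        again = lt.majority_consensus([cons, cons, cons]).consensus
        assert again == cons

    def test_unequal_lengths_raise(self):
        with pytest.raises(AlignmentShapeError):
            lt.majority_consensus(["AC", "ACG"])


class TestTranslation:
    def test_frame_plus_one(self):
        assert lt.six_frame_translate("ATGGCC")[1] == "MA"

    def test_reverse_frame_stop(self):
        assert lt.six_frame_translate("TTA")[-1] == "*"

    def test_frame_lengths_floor_division(self):
        frames = lt.six_frame_translate("ATGGCCA")  # length 7
        assert len(frames[1]) == 2
        assert len(frames[3]) == 1

    def test_ambiguity_translates_to_x(self):
        assert translate("ANG") == "X"

    def test_empty_raises(self):
        with pytest.raises(DegenerateSequenceError):
            lt.six_frame_translate("")


class TestStarAlign:
    def test_equal_length_ungapped_inputs_pass_through(self):
        seqs = ["ACGTACGT", "ACGTACGA", "ACCTACGT"]
        rows = lt.star_align(seqs)
        assert rows == seqs

    def test_projection_onto_longest(self):
        rows = lt.star_align(["ACGTACGT", "ACGTCGT"])  # one deletion
        assert len(rows[0]) == len(rows[1]) == 8
        assert rows[1].count("-") == 1
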