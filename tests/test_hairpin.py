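"""Folding, candidate excision, the energy filter and hairpin geometry."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirdup.config import FoldConfig
from mirdup.hairpin import (HairpinCandidate, energy_filter, excise_candidates,
                            fold_nussinov, qualify_hairpin, structure_pairs)
from mirdup.mapping import AlignmentHit, ReadStack
from mirdup.seqio import revcomp
from mirdup.synthetic import make_hairpin
from tests.oracles import max_pairs_enumeration

PC = FoldConfig(energy_model="pair_count")
STACKING = FoldConfig(energy_model="stacking")


class TestFoldNussinov:
    def test_simple_stem_loop(self):
        structure, mfe = fold_nussinov("GGGAAACCC", PC)
        assert structure == "(((...)))"
        assert structure.count("(") == max_pairs_enumeration("GGGAAACCC")
        assert mfe == PC.pair_energy * 3

    def test_poly_a_unpaired(self):
        structure, mfe = fold_nussinov("AAAAAAAAA", PC)
        assert structure == "." * 9 and mfe == 0.0

    def test_random_sequences_match_enumeration(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 13))
            seq = "".join(rng.choice(list("ACGU"), n))
            structure, _ = fold_nussinov(seq, PC)
            assert structure.count("(") == max_pairs_enumeration(seq)

    def test_t_u_spelling_invariance(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 40))
        assert fold_nussinov(seq, PC) == fold_nussinov(
            seq.replace("T", "U"), PC)
        assert fold_nussinov(seq, STACKING) == fold_nussinov(
            seq.replace("T", "U"), STACKING)

    def test_n_never_pairs(self):
        structure, _ = fold_nussinov("NNNNNNNNNN", PC)
        assert structure == "." * 10

    def test_too_short_returns_open(self):
        assert fold_nussinov("ACGU", PC) == ("....", 0.0)

    def test_mfe_equals_pair_energy_times_pairs(self, rng):
        seq = "".join(rng.choice(list("ACGU"), 60))
        structure, mfe = fold_nussinov(seq, PC)
        assert mfe == pytest.approx(PC.pair_energy * structure.count("("))

    def test_stacking_energy_nonpositive_and_consistent(self, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGU"), 50))
            structure, mfe = fold_nussinov(seq, STACKING)
            assert mfe <= 0.0
            structure_pairs(structure)  # brackets balanced

    @given(st.text(alphabet="ACGU", min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_structure_always_wellformed(self, seq):
        structure, _ = fold_nussinov(seq, PC)
        assert len(structure) == len(seq)
        partner = structure_pairs(structure)
        for i, j in enumerate(partner):
            if j != -1:
                assert partner[j] == i and abs(i - j) > PC.min_loop


class TestExciseCandidates:
    def _stack(self, start, end, strand="+", n=12):
        hits = [AlignmentHit(f"r{i}", "s", start, end, strand, 0)
                for i in range(n)]
        return ReadStack("s", strand, start, end, hits)

    def test_window_arithmetic(self):
        genome = {"s": "A" * 10_000}
        cands = excise_candidates(self._stack(1000, 1022), genome, PC)
        assert [(c.start, c.end) for c in cands] == [(1000, 1092), (930, 1022)]

    def test_clipped_at_scaffold_start(self):
        genome = {"s": "A" * 10_000}
        hits = [AlignmentHit(f"r{i}", "s", 5, 27, "+", 0) for i in range(3)]
        hits.append(AlignmentHit("r3", "s", 40, 62, "+", 0))
        stack = ReadStack("s", "+", 5, 62, hits)
        cands = excise_candidates(stack, genome, PC)
        assert any(c.start == 0 for c in cands)
        assert all(c.start >= 0 for c in cands)

    def test_minus_strand_sequence_reverse_complemented(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 2000))
        genome = {"s": seq}
        cands = excise_candidates(self._stack(900, 922, strand="-"), genome, PC)
        for c in cands:
            assert c.sequence == revcomp(seq[c.start:c.end])

    def test_wide_stack_gets_flankless_window(self):
        # a stack of 22-nt reads covering both arms is itself the precursor
        genome = {"s": "A" * 10_000}
        hits = [AlignmentHit(f"r{i}", "s", 1000, 1022, "+", 0)
                for i in range(5)]
        hits.append(AlignmentHit("r5", "s", 1038, 1060, "+", 0))
        stack = ReadStack("s", "+", 1000, 1060, hits)
        cands = excise_candidates(stack, genome, PC)
        assert (997, 1063) in {(c.start, c.end) for c in cands}


class TestEnergyFilter:
    def _cand(self, length, mfe):
        c = HairpinCandidate("s", 0, length, "+", "A" * length)
        c.mfe = mfe
        return c

    @pytest.mark.parametrize("length,mfe,kept", [
        (60, -15.0, True),   # -0.25 kcal/mol/nt
        (60, -6.0, False),   # -0.10
        (60, 0.0, False),
        (50, -10.0, True),   # exactly -0.2
    ])
    def test_threshold(self, length, mfe, kept):
        assert energy_filter(self._cand(length, mfe), PC) is kept


class TestQualifyHairpin:
    def _qualified(self, hairpin_seq, mature_start, mature_len=22,
                   config=STACKING, pad=""):
        seq = pad + hairpin_seq
        stack = ReadStack("s", "+", 0, len(seq), [
            AlignmentHit(f"r{i}", "s", len(pad) + mature_start,
                         len(pad) + mature_start + mature_len, "+", 0)
            for i in range(10)])
        cand = HairpinCandidate("s", 0, len(seq), "+", seq, stack)
        cand.structure, cand.mfe = fold_nussinov(seq, config)
        return qualify_hairpin(cand, stack, config)

    def test_perfect_hairpin_5p_mature(self, rng):
        hp = make_hairpin("ACGGATCGATCGATCGGATCGA", 8, bulges=0, rng=rng)
        cand = self._qualified(hp, 0)
        assert cand.rejection is None
        assert cand.mature_arm == "5p"
        assert cand.star_interval[0] >= cand.mature_interval[1]

    def test_perfect_hairpin_3p_mature(self, rng):
        hp = make_hairpin("ACGGATCGATCGATCGGATCGA", 8, bulges=0, rng=rng)
        cand = self._qualified(hp, len(hp) - 22)
        assert cand.rejection is None and cand.mature_arm == "3p"

    def test_mature_spanning_loop_rejected(self, rng):
        hp = make_hairpin("ACGGATCGATCGATCGGATCGA", 8, bulges=0, rng=rng)
        mid = len(hp) // 2 - 11
        cand = self._qualified(hp, mid)
        assert cand.rejection == "loop_overlap"

    def test_unpaired_mature_rejected(self):
        # mature region is poly-A with nothing to pair against
        seq = "A" * 30 + "GGGGCCCC" + "A" * 10
        stack = ReadStack("s", "+", 0, 22, [
            AlignmentHit("r", "s", 0, 22, "+", 0) for _ in range(5)])
        cand = HairpinCandidate("s", 0, len(seq), "+", seq, stack)
        cand.structure, cand.mfe = fold_nussinov(seq, PC)
        assert qualify_hairpin(cand, stack, PC).rejection == "underpaired"

    def test_modal_interval_outside_window_rejected(self, rng):
        hp = make_hairpin("ACGGATCGATCGATCGGATCGA", 8, bulges=0, rng=rng)
        stack = ReadStack("s", "+", 500, 522, [
            AlignmentHit("r", "s", 500, 522, "+", 0)])
        cand = HairpinCandidate("s", 0, len(hp), "+", hp, stack)
        cand.structure, cand.mfe = fold_nussinov(hp, STACKING)
        assert qualify_hairpin(cand, stack, STACKING).rejection == "outside"

    def test_mature_star_disjoint_invariant(self, rng):
        for bulges in (0, 1, 2):
            hp = make_hairpin("GTACGGATCCATCGATGGATCA", 10, bulges=bulges,
                              rng=rng)
            cand = self._qualified(hp, 0)
            if cand.rejection is None:
                m, s = cand.mature_interval, cand.star_interval
                assert s[1] <= m[0] or s[0] >= m[1]
                assert 0 <= m[0] < m[1] <= len(hp)
                assert 0 <= s[0] < s[1] <= len(hp)
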