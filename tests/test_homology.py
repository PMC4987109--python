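"""Local alignment, Karlin-Altschul statistics, ortholog search, families."""

from __future__ import annotations

from math import exp, log

import numpy as np
import pytest

from mirdup.config import AlignParams
from mirdup.homology import (CopyNumberMatrix, FamilyLocus, QueryHairpin,
                             cluster_families, confirm_ortholog, evalue,
                             karlin_altschul_lambda, local_align,
                             mature_similarity, search_genome,
                             species_copy_number)
from mirdup.seqio import revcomp
from mirdup.synthetic import _mutate, _random_seq, make_hairpin
from tests.oracles import best_local_score

P = AlignParams()


class TestLocalAlign:
    def test_self_alignment(self):
        aln = local_align("ACGTACGT", "ACGTACGT", P)
        assert aln.score == 16 and aln.identity == 1.0
        assert (aln.a_start, aln.a_end) == (0, 8)

    def test_heavily_substituted_copy_fails_identity_gate(self):
        a = "ACGTACGTACGTACGTACGTAC"
        b = "CCGAACTTAGGTCCGAACTTAC"  # substitutions at every 3rd position
        assert sum(x != y for x, y in zip(a, b)) == 7
        assert mature_similarity(a, b, P) == pytest.approx(15 / 22)
        assert mature_similarity(a, b, P) < P.min_identity

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(30):
            a = "".join(rng.choice(list("ACGT"), int(rng.integers(5, 15))))
            b = "".join(rng.choice(list("ACGT"), int(rng.integers(5, 15))))
            aln = local_align(a, b, P)
            assert aln.score == best_local_score(
                a, b, P.match, P.mismatch, P.gap_open, P.gap_extend)

    def test_score_symmetric(self, rng):
        a = "".join(rng.choice(list("ACGT"), 20))
        b = "".join(rng.choice(list("ACGT"), 20))
        assert local_align(a, b, P).score == local_align(b, a, P).score

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT", P)

    def test_alignment_strings_consistent(self, rng):
        a = "".join(rng.choice(list("ACGT"), 30))
        b = _mutate(a, 0.15, rng)
        aln = local_align(a, b, P)
        assert aln.aligned_a.replace("-", "") == a[aln.a_start:aln.a_end]
        assert aln.aligned_b.replace("-", "") == b[aln.b_start:aln.b_end]
        assert 0 <= aln.identity <= 1


class TestKarlinAltschul:
    def test_unit_scores_give_ln3(self):
        lam = karlin_altschul_lambda(1, -1)
        assert lam == pytest.approx(log(3), abs=1e-6)

    def test_blast_scores_satisfy_constraint(self):
        lam = karlin_altschul_lambda(2, -3)
        residual = 0.25 * exp(2 * lam) + 0.75 * exp(-3 * lam) - 1.0
        assert abs(residual) < 1e-9

    def test_nonnegative_expectation_rejected(self):
        with pytest.raises(ValueError):
            karlin_altschul_lambda(1, 0)

    def test_evalue_decreases_with_score(self):
        lam = karlin_altschul_lambda(2, -3)
        e1 = evalue(20, 60, 1_000_000, lam, 0.71)
        e2 = evalue(40, 60, 1_000_000, lam, 0.71)
        assert e2 < e1


def _query_from_hairpin(qid, hp, m=22):
    return QueryHairpin(qid, hp, (0, m), (len(hp) - m, len(hp)))


class TestSearchGenome:
    def _genome_with(self, rng, insert, n=30_000):
        pos = n // 2
        bg = _random_seq(rng, n)
        return {"s": bg[:pos] + insert + bg[pos:]}, pos

    def test_planted_paralog_found(self, rng):
        hp = make_hairpin("GTACGGATCCATCGATGGATCA", 12, rng=rng)
        paralog = _mutate(hp, 0.05, rng)
        genome, pos = self._genome_with(rng, paralog)
        hits = search_genome(_query_from_hairpin("q", hp), genome, P)
        assert len(hits) == 1
        h = hits[0]
        assert h.identity >= 0.9
        assert abs(h.start - pos) < 10 and h.strand == "+"

    def test_scrambled_query_finds_nothing(self, rng):
        hp = make_hairpin("GTACGGATCCATCGATGGATCA", 12, rng=rng)
        genome = {"s": _random_seq(rng, 30_000)}
        assert search_genome(_query_from_hairpin("q", hp), genome, P) == []

    def test_minus_strand_hit_symmetric(self, rng):
        hp = make_hairpin("GTACGGATCCATCGATGGATCA", 12, bulges=2, rng=rng)
        genome_f, pos = self._genome_with(rng, hp)
        genome_r = {"s": genome_f["s"][:pos] + revcomp(hp)
                    + genome_f["s"][pos + len(hp):]}
        q = _query_from_hairpin("q", hp)
        fwd = [h for h in search_genome(q, genome_f, P) if abs(h.start - pos) < 10]
        rev = [h for h in search_genome(q, genome_r, P) if abs(h.start - pos) < 10]
        assert fwd and rev
        assert {h.strand for h in fwd} >= {"+"} and {h.strand for h in rev} >= {"-"}
        assert max(h.score for h in fwd) == max(h.score for h in rev)


class TestConfirmOrtholog:
    def _hit_covering(self, query, q_lo, q_hi, identity=1.0, rng=None):
        """Hit whose alignment covers query positions [q_lo, q_hi)."""
        from mirdup.homology import OrthologHit, LocalAlignment
        cols = []
        rng = rng or np.random.default_rng(0)
        for qp in range(q_lo, q_hi):
            cols.append((qp, rng.random() < identity))
        aln = LocalAlignment(0, q_lo, q_hi, 0, q_hi - q_lo, "", "")
        return OrthologHit("q", "", "s", 0, q_hi - q_lo, "+", 0, identity,
                           aln, query_columns=cols)

    def test_full_arm_high_identity_confirmed(self, rng):
        hp = make_hairpin("GTACGGATCCATCGATGGATCA", 12, rng=rng)
        q = _query_from_hairpin("q", hp)
        hit = self._hit_covering(q, 0, len(hp))
        assert confirm_ortholog(hit, q, P)

    def test_loop_only_hit_rejected(self, rng):
        hp = make_hairpin("GTACGGATCCATCGATGGATCA", 12, rng=rng)
        q = _query_from_hairpin("q", hp)
        hit = self._hit_covering(q, 23, len(hp) - 23)
        assert not confirm_ortholog(hit, q, P)

    def test_half_arm_coverage_rejected(self, rng):
        hp = make_hairpin("GTACGGATCCATCGATGGATCA", 12, rng=rng)
        q = _query_from_hairpin("q", hp)
        hit = self._hit_covering(q, 11, len(hp) - 11)  # half of each arm
        assert not confirm_ortholog(hit, q, P)


class TestClusterFamilies:
    def _locus(self, lid, species, start, matures):
        return FamilyLocus(lid, species, "s", start, start + 60, "+", matures)

    def test_identical_copies_form_multicopy_family(self):
        m = "GTACGGATCCATCGATGGATCA"
        loci = [self._locus(f"l{i}", "A", i * 1000, [m]) for i in range(3)]
        fams = cluster_families(loci, P)
        assert len(fams) == 1
        matrix = CopyNumberMatrix.from_families(fams)
        assert matrix.counts.iloc[0]["A"] == 3
        assert matrix.classify().iloc[0]["A"] == "multicopy"

    def test_two_copies_classified_multicopy(self):
        m = "GTACGGATCCATCGATGGATCA"
        fams = cluster_families(
            [self._locus("a", "A", 0, [m]), self._locus("b", "A", 5000, [m])], P)
        matrix = CopyNumberMatrix.from_families(fams)
        assert matrix.classify().iloc[0]["A"] == "multicopy"
        assert matrix.multicopy_families("A") == list(matrix.counts.index)

    def test_dissimilar_families_never_merge(self, rng):
        a = "GTACGGATCCATCGATGGATCA"
        b = _mutate(a, 0.5, rng)
        while mature_similarity(a, b, P) >= P.min_identity:
            b = _mutate(a, 0.5, rng)
        fams = cluster_families(
            [self._locus("a", "A", 0, [a]), self._locus("b", "A", 5000, [b])], P)
        assert len(fams) == 2

    def test_input_order_invariance(self, rng):
        loci = []
        for i in range(4):
            m = _random_seq(rng, 22)
            loci.append(self._locus(f"l{i}", "A", i * 1000, [m]))
        fams1 = cluster_families(loci, P)
        fams2 = cluster_families(list(reversed(loci)), P)
        assert {tuple(sorted(l.id for l in v)) for v in fams1.values()} == \
            {tuple(sorted(l.id for l in v)) for v in fams2.values()}

    def test_known_name_preferred(self):
        m = "GTACGGATCCATCGATGGATCA"
        loci = [self._locus("a", "A", 0, [m])]
        loci[0].known_name = "mir-71"
        assert list(cluster_families(loci, P)) == ["mir-71"]


class TestSpeciesCopyNumber:
    def test_planted_copies_recovered_across_genomes(self, rng):
        mature = "GTACGGATCCATCGATGGATCA"
        hp = make_hairpin(mature, 12, bulges=2, rng=rng)
        copies = {"A": 2, "B": 3}
        genomes = {}
        for sp, n in copies.items():
            parts = []
            for _ in range(n):
                parts += [_random_seq(rng, 3000), _mutate(hp, 0.05, rng)]
            parts.append(_random_seq(rng, 3000))
            genomes[sp] = {f"{sp}_s": "".join(parts)}
        queries = [QueryHairpin("q", hp, (0, 22), (len(hp) - 22, len(hp)),
                                family="famX")]
        matrix, hits = species_copy_number(queries, genomes, P)
        assert matrix.counts.loc["famX", "A"] == 2
        assert matrix.counts.loc["famX", "B"] == 3
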