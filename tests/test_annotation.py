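"""The three retention criteria and their exact boundary semantics."""

from __future__ import annotations

import numpy as np
import pytest

from mirdup.annotation import (GenomeScanner, MiRNACall, Rejection,
                               apply_filters, dedup_calls,
                               five_prime_homogeneity, name_calls)
from mirdup.config import FilterConfig, FoldConfig
from mirdup.hairpin import HairpinCandidate, fold_nussinov, qualify_hairpin
from mirdup.mapping import AlignmentHit, ReadStack
from mirdup.seqio import revcomp
from mirdup.synthetic import make_hairpin

STACKING = FoldConfig(energy_model="stacking")


class TestFivePrimeHomogeneity:
    @pytest.mark.parametrize("counts,expected", [
        ({100: 6, 101: 4}, 0.6),
        ({100: 5, 101: 5}, 0.5),
        ({100: 10}, 1.0),
    ])
    def test_values(self, counts, expected):
        assert five_prime_homogeneity(counts) == pytest.approx(expected)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            five_prime_homogeneity({})


def _random_background(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestCountCrossLoci:
    def test_planted_once(self, rng):
        mature = "GTACGGATCCATCGATGGATCA"
        genome = {"g": _random_background(rng, 3000) + mature
                  + _random_background(rng, 3000)}
        assert GenomeScanner(genome).count_loci(mature, 0) == 1

    def test_twelve_verbatim_copies(self, rng):
        mature = "GTACGGATCCATCGATGGATCA"
        parts = [_random_background(rng, 300) + mature for _ in range(12)]
        genome = {"g": "".join(parts) + _random_background(rng, 300)}
        assert GenomeScanner(genome).count_loci(mature, 0) == 12

    def test_two_mismatch_copy_counted_at_tolerance(self, rng):
        mature = "GTACGGATCCATCGATGGATCA"
        variant = "GAACGGATCCATCGATGGATCT"  # 2 substitutions
        genome = {"g": _random_background(rng, 500) + mature
                  + _random_background(rng, 500) + variant
                  + _random_background(rng, 500)}
        scanner = GenomeScanner(genome)
        assert scanner.count_loci(mature, 0) == 1
        assert scanner.count_loci(mature, 2) == 2

    def test_reverse_strand_match_counted(self, rng):
        mature = "GTACGGATCCATCGATGGATCA"
        genome = {"g": _random_background(rng, 500) + revcomp(mature)
                  + _random_background(rng, 500)}
        assert GenomeScanner(genome).count_loci(mature, 0) == 1

    def test_adjacent_matches_collapse(self):
        # 'AAAA...' matches a poly-A query at every offset: one locus
        genome = {"g": "C" * 50 + "A" * 40 + "C" * 50}
        assert GenomeScanner(genome).count_loci("A" * 22, 0) == 1


def build_locus(rng, five_prime_counts, extra_copies=0):
    """Plant one hairpin, optionally extra mature copies, and build the
    qualified candidate plus a stack with a chosen 5'-end distribution.

    The hairpin carries two stem bulges (from a fixed generator, so every
    call folds identically): a perfect stem would make the 3p arm an exact
    antisense copy of the mature and perturb the cross-locus counts.
    """
    mature = "GTACGGATCCATCGATGGATCA"
    hp = make_hairpin(mature, 12, bulges=2, rng=np.random.default_rng(123))
    parts = [_random_background(rng, 1000), hp]
    for _ in range(extra_copies):
        parts += [_random_background(rng, 200), mature]
    parts.append(_random_background(rng, 1000))
    genome = {"g": "".join(parts)}
    offset = 1000
    hits = []
    i = 0
    for shift, count in five_prime_counts.items():
        for _ in range(count):
            hits.append(AlignmentHit(f"r{i}", "g", offset + shift,
                                     offset + shift + 22, "+", 0))
            i += 1
    stack = ReadStack("g", "+", min(h.start for h in hits),
                      max(h.end for h in hits), hits)
    cand = HairpinCandidate("g", offset, offset + len(hp), "+", hp, stack)
    cand.structure, cand.mfe = fold_nussinov(hp, STACKING)
    cand = qualify_hairpin(cand, stack, STACKING)
    assert cand.rejection is None
    return cand, stack, GenomeScanner(genome)


class TestFilterBoundaries:
    def test_nine_reads_discarded_ten_retained(self, rng):
        cand, stack, scanner = build_locus(rng, {0: 9})
        res = apply_filters(cand, stack, scanner, FilterConfig())
        assert isinstance(res, Rejection) and res.reasons == ["low_reads"]
        cand, stack, scanner = build_locus(rng, {0: 10})
        res = apply_filters(cand, stack, scanner, FilterConfig())
        assert isinstance(res, MiRNACall)

    def test_homogeneity_049_discarded_050_retained(self, rng):
        cand, stack, scanner = build_locus(rng, {0: 49, 1: 26, -1: 25})
        res = apply_filters(cand, stack, scanner, FilterConfig())
        assert isinstance(res, Rejection) and "poor_processing" in res.reasons
        cand, stack, scanner = build_locus(rng, {0: 50, 1: 25, -1: 25})
        res = apply_filters(cand, stack, scanner, FilterConfig())
        assert isinstance(res, MiRNACall)

    def test_eleven_cross_loci_discarded_ten_retained(self, rng):
        cand, stack, scanner = build_locus(rng, {0: 20}, extra_copies=10)
        res = apply_filters(cand, stack, scanner, FilterConfig())
        assert isinstance(res, Rejection) and res.reasons == ["repetitive"]
        cand, stack, scanner = build_locus(rng, {0: 20}, extra_copies=9)
        res = apply_filters(cand, stack, scanner, FilterConfig())
        assert isinstance(res, MiRNACall)

    def test_all_reasons_recorded_without_short_circuit(self, rng):
        cand, stack, scanner = build_locus(rng, {0: 4, 1: 3, 2: 2},
                                           extra_copies=10)
        res = apply_filters(cand, stack, scanner, FilterConfig())
        assert isinstance(res, Rejection)
        assert set(res.reasons) == {"low_reads", "poor_processing",
                                    "repetitive"}
        assert len(res.candidate.stack.reads) == 9

    def test_monotone_in_min_reads(self, rng):
        cand, stack, scanner = build_locus(rng, {0: 15})
        kept_low = isinstance(
            apply_filters(cand, stack, scanner, FilterConfig(min_reads=10)),
            MiRNACall)
        kept_high = isinstance(
            apply_filters(cand, stack, scanner, FilterConfig(min_reads=16)),
            MiRNACall)
        assert kept_low and not kept_high


class TestCallsBookkeeping:
    def test_retained_call_passes_all_criteria(self, rng):
        cand, stack, scanner = build_locus(rng, {0: 40})
        call = apply_filters(cand, stack, scanner, FilterConfig())
        assert isinstance(call, MiRNACall)
        assert all(ok for _, ok in call.filter_trace)
        assert call.total_reads == 40
        assert call.dominant_arm in ("5p", "3p")
        dominant = call.mature(call.dominant_arm)
        assert dominant.unique_in_genome
        assert dominant.sequence == "GTACGGATCCATCGATGGATCA"

    def test_dedup_keeps_best_supported(self, rng):
        cand_a, stack_a, scanner = build_locus(rng, {0: 40})
        call_a = apply_filters(cand_a, stack_a, scanner, FilterConfig())
        cand_b, stack_b, _ = build_locus(rng, {0: 12})
        call_b = apply_filters(cand_b, stack_b, scanner, FilterConfig())
        merged = dedup_calls([call_a, call_b])
        assert len(merged) == 1 and merged[0].total_reads == 40

    def test_name_calls_deterministic(self, rng):
        calls = []
        for start in (5000, 1000, 3000):
            cand, stack, scanner = build_locus(rng, {0: 20})
            call = apply_filters(cand, stack, scanner, FilterConfig())
            call.hairpin.start = start
            call.family = "9"
            calls.append(call)
        named = name_calls(calls, prefix="sp")
        assert [c.name for c in named] == ["sp-mir-9-1", "sp-mir-9-2",
                                           "sp-mir-9-3"]
        assert [c.start for c in named] == [1000, 3000, 5000]

    def test_unassigned_calls_keep_cand_names(self, rng):
        cand, stack, scanner = build_locus(rng, {0: 20})
        call = apply_filters(cand, stack, scanner, FilterConfig())
        call.family = None
        (named,) = name_calls([call])
        assert named.name.startswith("cand-")
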