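"""Scoring pipeline output against the simulator's ground truth.

Only meaningful for synthetic runs: planted loci, the planted copy-number
matrix and planted arm biases are known, so discovery recall/precision,
matrix recovery, duplicated-cluster recovery and arm-switch calls can all
be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from mirdup.annotation import MiRNACall
from mirdup.clusters import GenomicCluster
from mirdup.homology import OrthologHit
from mirdup.synthetic import PlantedLocus


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def match_call(scaffold: str, start: int, end: int,
               truth: list[PlantedLocus]) -> PlantedLocus | None:
    """The planted locus a detected interval corresponds to, if any.

    An interval matches when it covers at least half of the planted hairpin
    or at least half of either planted mature product — the mature is the
    functional unit that defines a locus, and detected precursor boundaries
    may legitimately lean into the flank on the star side.
    """
    for t in truth:
        if t.scaffold != scaffold:
            continue
        if _overlap(start, end, t.start, t.end) >= (t.end - t.start) / 2:
            return t
        for arm in ("5p", "3p"):
            m0, m1 = t.mature_interval(arm)
            if _overlap(start, end, m0, m1) >= (m1 - m0) / 2:
                return t
    return None


@dataclass
class RecoveryScore:
    recall: float
    precision: float
    n_planted: int
    n_called: int
    n_truth_matched: int
    n_calls_matched: int


def score_calls(calls: list[MiRNACall], truth: list[PlantedLocus]) -> RecoveryScore:
    """Planted-locus recall and call precision by coordinate overlap."""
    matched_truth: set[tuple[str, int]] = set()
    matched_calls = 0
    for call in calls:
        t = match_call(call.scaffold, call.start, call.end, truth)
        if t is not None:
            matched_calls += 1
            matched_truth.add((t.scaffold, t.start))
    n_planted = len(truth)
    recall = len(matched_truth) / n_planted if n_planted else 1.0
    precision = matched_calls / len(calls) if calls else 1.0
    return RecoveryScore(recall, precision, n_planted, len(calls),
                         len(matched_truth), matched_calls)


def planted_matrix(truth_by_species: dict[str, list[PlantedLocus]]) -> pd.DataFrame:
    """The true family x species copy-number matrix."""
    species = sorted(truth_by_species)
    fams = sorted({t.family for ts in truth_by_species.values() for t in ts})
    df = pd.DataFrame(0, index=fams, columns=species, dtype=int)
    for sp, ts in truth_by_species.items():
        for t in ts:
            df.loc[t.family, sp] += 1
    return df


def recovered_matrix(hits_by_species: dict[str, list[OrthologHit]],
                     truth_by_species: dict[str, list[PlantedLocus]]
                     ) -> tuple[pd.DataFrame, int]:
    """Relabel recovered loci by the planted family they overlap.

    Returns the relabeled matrix plus the count of recovered loci that
    overlap no planted locus (false loci).  The matrix is exact when it
    equals :func:`planted_matrix` and the false count is zero.
    """
    species = sorted(truth_by_species)
    fams = sorted({t.family for ts in truth_by_species.values() for t in ts})
    df = pd.DataFrame(0, index=fams, columns=species, dtype=int)
    false_loci = 0
    for sp, hits in hits_by_species.items():
        for h in hits:
            t = match_call(h.scaffold, h.start, h.end, truth_by_species[sp])
            if t is None:
                false_loci += 1
            else:
                df.loc[t.family, sp] += 1
    return df, false_loci


def matrix_exact(hits_by_species: dict[str, list[OrthologHit]],
                 truth_by_species: dict[str, list[PlantedLocus]]) -> bool:
    rec, false_loci = recovered_matrix(hits_by_species, truth_by_species)
    return false_loci == 0 and rec.equals(planted_matrix(truth_by_species))


def cluster_recovered(groups: list[list[GenomicCluster]],
                      truth: list[PlantedLocus],
                      cluster_families: set[str]) -> bool:
    """True when some duplicate-cluster group consists of (at least) two
    clusters whose members map to the planted cluster families."""
    regions = _planted_cluster_regions(truth, cluster_families)
    if len(regions) < 2:
        return False
    for group in groups:
        covered = set()
        for cluster in group:
            for i, (scaf, s, e) in enumerate(regions):
                if cluster.scaffold == scaf and _overlap(cluster.start, cluster.end, s, e) > 0:
                    covered.add(i)
        if len(covered) >= 2:
            return True
    return False


def _planted_cluster_regions(truth: list[PlantedLocus],
                             families: set[str]) -> list[tuple[str, int, int]]:
    """Contiguous planted regions made of the duplicated-cluster families."""
    members = sorted((t for t in truth if t.family in families),
                     key=lambda t: (t.scaffold, t.start))
    regions: list[tuple[str, int, int]] = []
    for t in members:
        if regions and regions[-1][0] == t.scaffold \
                and t.start - regions[-1][2] < 10_000:
            regions[-1] = (t.scaffold, regions[-1][1], t.end)
        else:
            regions.append((t.scaffold, t.start, t.end))
    return regions
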