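"""Genomic miRNA clusters, tandem arrays and duplicated-cluster groups.

Loci on one scaffold are chained into clusters when successive gaps stay
within ``max_gap`` (50 kb by default, the span of the spider's tandem
mir-3791 expansion).  Two clusters with sufficiently similar family sets
(Jaccard over families, not copy counts — duplicated clusters routinely
diverge in copy number) at different genomic locations are grouped as
putative cluster paralogs; clusters hugging a scaffold end are flagged as
possible assembly fragments.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from mirdup.config import ClusterConfig


@dataclass
class MiRNALocus:
    family: str
    species: str
    scaffold: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""


@dataclass
class GenomicCluster:
    scaffold: str
    members: list[MiRNALocus] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.members[0].start

    @property
    def end(self) -> int:
        return self.members[-1].end

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def composition(self) -> Counter:
        """Multiset family -> copy count."""
        return Counter(m.family for m in self.members)

    def distance_to_scaffold_ends(self, scaffold_length: int) -> tuple[int, int]:
        return self.start, scaffold_length - self.end


def detect_clusters(loci: list[MiRNALocus], config: ClusterConfig | None = None
                    ) -> tuple[list[GenomicCluster], list[MiRNALocus]]:
    """Chain loci per scaffold into clusters; returns (clusters, singletons).

    Every locus lands in exactly one chain or singleton list; input order
    is irrelevant (loci are sorted by coordinate internally).
    """
    cfg = config or ClusterConfig()
    by_scaf: dict[str, list[MiRNALocus]] = {}
    for loc in loci:
        by_scaf.setdefault(loc.scaffold, []).append(loc)
    clusters: list[GenomicCluster] = []
    singles: list[MiRNALocus] = []
    for scaf in sorted(by_scaf):
        chain: list[MiRNALocus] = []
        for loc in sorted(by_scaf[scaf], key=lambda l: (l.start, l.end)):
            if chain and loc.start - chain[-1].end <= cfg.max_gap:
                chain.append(loc)
            else:
                if len(chain) >= cfg.min_members:
                    clusters.append(GenomicCluster(scaf, chain))
                elif chain:
                    singles.extend(chain)
                chain = [loc]
        if len(chain) >= cfg.min_members:
            clusters.append(GenomicCluster(scaf, chain))
        elif chain:
            singles.extend(chain)
    return clusters, singles


def _jaccard(a: set[str], b: set[str]) -> float:
    return len(a & b) / len(a | b) if a | b else 0.0


def find_duplicated_clusters(clusters: list[GenomicCluster],
                             config: ClusterConfig | None = None
                             ) -> list[list[GenomicCluster]]:
    """Group putative cluster paralogs by family-set Jaccard similarity.

    Two clusters pair when Jaccard(family sets) >= the threshold and they
    occupy different scaffolds or non-overlapping spans; groups are the
    transitive closure of pairing, and only groups of >= 2 are returned.
    """
    cfg = config or ClusterConfig()
    n = len(clusters)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = clusters[i], clusters[j]
            same_place = (a.scaffold == b.scaffold
                          and not (a.end <= b.start or b.end <= a.start))
            if same_place:
                continue
            if _jaccard(set(a.composition), set(b.composition)) \
                    >= cfg.composition_jaccard_min:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[GenomicCluster]] = {}
    for i, c in enumerate(clusters):
        groups.setdefault(find(i), []).append(c)
    return [sorted(g, key=lambda c: (c.scaffold, c.start))
            for root, g in sorted(groups.items()) if len(g) >= 2]


def tandem_arrays(loci: list[MiRNALocus], config: ClusterConfig | None = None
                  ) -> dict[str, list[list[MiRNALocus]]]:
    """Maximal runs of >= 2 same-family loci on one scaffold within
    ``max_gap`` of each other.  Loci of other families interleaved inside a
    run do not break it (the mir-71/mir-2 arrangement)."""
    cfg = config or ClusterConfig()
    by_key: dict[tuple[str, str], list[MiRNALocus]] = {}
    for loc in loci:
        by_key.setdefault((loc.family, loc.scaffold), []).append(loc)
    arrays: dict[str, list[list[MiRNALocus]]] = {}
    for (fam, _scaf), group in sorted(by_key.items()):
        group.sort(key=lambda l: (l.start, l.end))
        run: list[MiRNALocus] = []
        for loc in group:
            if run and loc.start - run[-1].end <= cfg.max_gap:
                run.append(loc)
            else:
                if len(run) >= 2:
                    arrays.setdefault(fam, []).append(run)
                run = [loc]
        if len(run) >= 2:
            arrays.setdefault(fam, []).append(run)
    return arrays


def flag_scaffold_ends(cluster: GenomicCluster, scaffold_length: int,
                       config: ClusterConfig | None = None) -> bool:
    """True when the cluster lies within ``end_flag_distance`` of either
    scaffold end — a hint that it may be a fragment of a larger cluster."""
    cfg = config or ClusterConfig()
    return min(cluster.distance_to_scaffold_ends(scaffold_length)) \
        <= cfg.end_flag_distance
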