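"""Final microRNA calls: the three read-based retention criteria.

A qualified hairpin becomes a call only if it clears all of: at least
``min_reads`` reads at the locus; at least half of the dominant mature's
reads sharing the modal 5' end (precise Dicer processing); and the dominant
mature matching at most ``max_cross_loci`` genomic loci at up to two
substitutions (repeat-derived sequences are unreliable).  All three
criteria are always evaluated and recorded — rejection reasons are data,
not exceptions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from mirdup.config import FilterConfig
from mirdup.hairpin import HairpinCandidate
from mirdup.mapping import AlignmentHit, ReadStack
from mirdup.seqio import revcomp


def five_prime_homogeneity(stack_positions: dict[int, int] | Counter) -> float:
    """Fraction of reads sharing the modal 5'-end position."""
    total = sum(stack_positions.values())
    if total == 0:
        raise ValueError("five_prime_homogeneity of an empty position map")
    return max(stack_positions.values()) / total


class GenomeScanner:
    """Mismatch-tolerant scanner over a genome (both strands).

    Candidate positions come from exact 7-mer seeds (pigeonhole: a query
    split into ``max_mm + 1`` chunks must match one chunk exactly), then
    each candidate is verified base-by-base.  Overlapping matches within
    1 nt on the same strand collapse into one locus.
    """

    def __init__(self, genome: dict[str, str], seed_k: int = 7):
        from mirdup.mapping import KmerIndex
        self.genome = genome
        self._index = KmerIndex(genome, seed_k)
        self._k = seed_k

    def _positions(self, query: str, max_mm: int) -> list[tuple[str, str, int]]:
        k = self._k
        if len(query) < k * (max_mm + 1):
            raise ValueError(
                f"query of {len(query)} nt too short for {max_mm}-mismatch "
                f"scanning with {k}-mer seeds")
        out = set()
        for strand, q in (("+", query), ("-", revcomp(query))):
            chunk = len(q) // (max_mm + 1)
            for c in range(max_mm + 1):
                off = c * chunk
                for name, pos in self._index.lookup(q[off:off + k]):
                    start = pos - off
                    if start < 0 or start + len(q) > len(self.genome[name]):
                        continue
                    target = self.genome[name][start:start + len(q)]
                    mm = sum(x != y for x, y in zip(q, target))
                    if mm <= max_mm:
                        out.add((name, strand, start))
        return sorted(out)

    def count_loci(self, query: str, max_mm: int) -> int:
        """Distinct loci matching ``query`` with <= ``max_mm`` substitutions."""
        positions = sorted(self._positions(query, max_mm))
        loci, prev = 0, None
        for name, strand, pos in positions:
            if prev is not None and prev[0] == name and prev[1] == strand \
                    and pos - prev[2] <= 1:
                prev = (name, strand, pos)
                continue
            loci += 1
            prev = (name, strand, pos)
        return loci


@dataclass
class MatureProduct:
    sequence: str
    arm: str  # 5p | 3p
    read_count: int
    five_prime_homogeneity: float
    unique_in_genome: bool
    interval: tuple[int, int] | None = None  # genomic
    read_ids: list[str] = field(default_factory=list)


@dataclass
class MiRNACall:
    name: str
    hairpin: HairpinCandidate
    mature5p: MatureProduct | None
    mature3p: MatureProduct | None
    dominant_arm: str  # 5p | 3p | tie
    total_reads: int
    filter_trace: list[tuple[str, bool]] = field(default_factory=list)
    family: str | None = None

    @property
    def scaffold(self) -> str:
        return self.hairpin.scaffold

    @property
    def start(self) -> int:
        return self.hairpin.start

    @property
    def end(self) -> int:
        return self.hairpin.end

    def mature(self, arm: str) -> MatureProduct | None:
        return self.mature5p if arm == "5p" else self.mature3p


@dataclass
class Rejection:
    candidate: HairpinCandidate
    reasons: list[str]


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _arm_reads(candidate: HairpinCandidate, stack: ReadStack
               ) -> dict[str, list[AlignmentHit]]:
    """Assign stack reads to the mature or star arm by larger overlap."""
    assert candidate.mature_interval is not None
    mature_g = candidate.to_genomic(*candidate.mature_interval)
    star_g = candidate.to_genomic(*candidate.star_interval)
    mature_g = tuple(sorted(mature_g))
    star_g = tuple(sorted(star_g))
    arms: dict[str, list[AlignmentHit]] = {"mature": [], "star": []}
    for h in stack.reads:
        iv = (h.start, h.end)
        if _overlap(iv, mature_g) >= _overlap(iv, star_g):
            arms["mature"].append(h)
        else:
            arms["star"].append(h)
    return arms


def _product(candidate: HairpinCandidate, reads: list[AlignmentHit], arm: str,
             genome: dict[str, str], scanner: GenomeScanner) -> MatureProduct | None:
    if not reads:
        return None
    c = Counter((h.start, h.end) for h in reads)
    top = max(c.values())
    s, e = min(iv for iv, n in c.items() if n == top)
    seq = genome[candidate.scaffold][s:e]
    if candidate.strand == "-":
        seq = revcomp(seq)
    ends = Counter(h.start if candidate.strand == "+" else h.end for h in reads)
    return MatureProduct(
        sequence=seq, arm=arm, read_count=len(reads),
        five_prime_homogeneity=five_prime_homogeneity(ends),
        unique_in_genome=scanner.count_loci(seq, 0) == 1,
        interval=(s, e), read_ids=sorted(h.read_id for h in reads))


def apply_filters(candidate: HairpinCandidate, stack: ReadStack,
                  scanner: GenomeScanner, config: FilterConfig
                  ) -> MiRNACall | Rejection:
    """Evaluate the three retention criteria on one qualified candidate.

    Boundary semantics follow the stated criteria exactly: discarded at
    <= min_reads - 1 reads, at homogeneity < min_homogeneity (exactly 50%
    passes), and at > max_cross_loci loci (exactly 10 passes).
    """
    genome = scanner.genome
    arms = _arm_reads(candidate, stack)
    mature_arm = candidate.mature_arm
    star_arm = "3p" if mature_arm == "5p" else "5p"
    dominant = _product(candidate, arms["mature"], mature_arm, genome, scanner)
    other = _product(candidate, arms["star"], star_arm, genome, scanner)
    assert dominant is not None  # the modal interval always has reads

    total = stack.n_reads
    cross = scanner.count_loci(dominant.sequence, config.cross_mismatch)
    trace = [
        ("min_reads", total >= config.min_reads),
        ("five_prime_homogeneity",
         dominant.five_prime_homogeneity >= config.min_homogeneity),
        ("cross_loci", cross <= config.max_cross_loci),
    ]
    if not all(ok for _, ok in trace):
        reasons = [{"min_reads": "low_reads",
                    "five_prime_homogeneity": "poor_processing",
                    "cross_loci": "repetitive"}[name]
                   for name, ok in trace if not ok]
        return Rejection(candidate, reasons)

    m5, m3 = (dominant, other) if mature_arm == "5p" else (other, dominant)
    c5 = m5.read_count if m5 else 0
    c3 = m3.read_count if m3 else 0
    dom = "5p" if c5 > c3 else "3p" if c3 > c5 else "tie"
    return MiRNACall(
        name=f"cand-{candidate.scaffold}-{candidate.start}",
        hairpin=candidate, mature5p=m5, mature3p=m3, dominant_arm=dom,
        total_reads=total, filter_trace=trace)


def dedup_calls(calls: list[MiRNACall]) -> list[MiRNACall]:
    """Merge calls whose hairpin windows overlap on one scaffold, keeping
    the best-supported (most reads, then lowest energy/nt).

    Strand is deliberately ignored: the two arms of a duplex are near
    reverse complements, so reads from one arm also map antisense onto the
    other and can seed a mirror-image call of the same locus.
    """
    calls = sorted(calls, key=lambda c: (c.scaffold, c.start, c.hairpin.strand))
    kept: list[MiRNACall] = []
    for call in calls:
        prev = kept[-1] if kept else None
        if (prev is not None and prev.scaffold == call.scaffold
                and _overlap((prev.start, prev.end), (call.start, call.end)) > 0):
            better = max(prev, call, key=lambda c: (c.total_reads,
                                                    -c.hairpin.mfe_per_nt))
            kept[-1] = better
        else:
            kept.append(call)
    return kept


def annotate(qualified: list[HairpinCandidate], genome: dict[str, str],
             config: FilterConfig | None = None
             ) -> tuple[list[MiRNACall], list[Rejection]]:
    """Filter all qualified candidates and deduplicate overlapping calls."""
    config = config or FilterConfig()
    scanner = GenomeScanner(genome)
    calls, rejections = [], []
    for cand in qualified:
        res = apply_filters(cand, cand.stack, scanner, config)
        (calls if isinstance(res, MiRNACall) else rejections).append(res)
    return dedup_calls(calls), rejections


def name_calls(calls: list[MiRNACall], prefix: str = "ptep") -> list[MiRNACall]:
    """Stable names: ``cand-<scaffold>-<start>`` until a family is assigned,
    then ``<prefix>-mir-<family>-<n>`` with suffixes ordered by coordinate."""
    calls = sorted(calls, key=lambda c: (c.scaffold, c.start))
    per_family: Counter = Counter()
    for call in calls:
        if call.family is None:
            call.name = f"cand-{call.scaffold}-{call.start}"
            continue
        per_family[call.family] += 1
        call.name = f"{prefix}-mir-{call.family}-{per_family[call.family]}"
    return calls
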