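"""Exact-match, best-stratum, multi-locus read mapping and read stacks.

The mapper reproduces a bowtie1-style contract: report every placement in
the best stratum (fewest mismatches, 0 by default), and discard the read
entirely as a multimapper when that stratum holds more than ``max_loci``
placements — retaining up to five placements lets reads from paralogous
miRNA copies count at every copy.  A k-mer index (k=12) anchors the search;
reads shorter than k fall back to a brute-force scan.  All coordinates are
0-based half-open on the forward strand; minus-strand placements are found
by mapping the reverse complement of the read.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from mirdup.config import MapConfig
from mirdup.seqio import FastqRecord, revcomp


@dataclass
class AlignmentHit:
    read_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    mismatches: int


@dataclass
class MapResult:
    """Outcome for one read: its best-stratum hits or a discard reason."""

    read_id: str
    status: str  # mapped | multimap | unmapped
    hits: list[AlignmentHit] = field(default_factory=list)


_BASE_CODE = np.zeros(256, dtype=np.int64)
_BASE_CODE[ord("C")] = 1
_BASE_CODE[ord("G")] = 2
_BASE_CODE[ord("T")] = 3


class KmerIndex:
    """Sorted-array k-mer index over one strand of a set of scaffolds.

    Sequences are 2-bit encoded and rolled into k-mer codes with NumPy, so
    building stays cheap even for megabase genomes.  Lookup is a binary
    search returning every (scaffold, position) carrying the word.
    Ambiguous bases are coded as 'A'; every downstream use re-verifies
    matches against the actual sequence.
    """

    def __init__(self, genome: dict[str, str], k: int):
        if k > 31:
            raise ValueError("k must fit 2-bit encoding (k <= 31)")
        self.genome = genome
        self.k = k
        self.total = sum(len(s) for s in genome.values())
        self.names = list(genome)
        codes_all, pos_all, scaf_all = [], [], []
        weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        for si, name in enumerate(self.names):
            seq = genome[name]
            if len(seq) < k:
                continue
            enc = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
            win = np.lib.stride_tricks.sliding_window_view(enc, k)
            codes = win @ weights
            codes_all.append(codes)
            pos_all.append(np.arange(len(codes), dtype=np.int64))
            scaf_all.append(np.full(len(codes), si, dtype=np.int32))
        codes = np.concatenate(codes_all) if codes_all else np.empty(0, np.int64)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = (np.concatenate(pos_all) if pos_all else np.empty(0, np.int64))[order]
        self._scaf = (np.concatenate(scaf_all) if scaf_all else np.empty(0, np.int32))[order]
        self._weights = weights

    def lookup(self, word: str) -> list[tuple[str, int]]:
        if len(word) != self.k or any(b not in "ACGT" for b in word):
            return []
        code = int(_BASE_CODE[np.frombuffer(word.encode(), dtype=np.uint8)]
                   @ self._weights)
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        return [(self.names[self._scaf[i]], int(self._pos[i]))
                for i in range(lo, hi)]


class GenomeIndex(KmerIndex):
    """Mapping index (k defaults to 12 via MapConfig)."""

    def __init__(self, genome: dict[str, str], k: int = 12):
        super().__init__(genome, k)

    def candidates(self, seq: str) -> set[tuple[str, int]]:
        """Candidate start positions for an exact or near-exact match,
        anchored by non-overlapping k-mer seeds (pigeonhole over mismatches)."""
        out: set[tuple[str, int]] = set()
        k = self.k
        for off in range(0, len(seq) - k + 1, k):
            for name, pos in self.lookup(seq[off:off + k]):
                start = pos - off
                if start >= 0 and start + len(seq) <= len(self.genome[name]):
                    out.add((name, start))
        return out


def _mismatches(a: str, b: str, limit: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def _scan_placements(index: GenomeIndex, seq: str, strand: str,
                     max_mm: int, brute: bool) -> list[tuple[str, int, int, str, int]]:
    found = []
    if brute:
        cands: Iterable[tuple[str, int]] = (
            (name, i) for name, g in index.genome.items()
            for i in range(len(g) - len(seq) + 1))
    else:
        cands = index.candidates(seq)
    for name, start in cands:
        mm = _mismatches(seq, index.genome[name][start:start + len(seq)], max_mm)
        if mm <= max_mm:
            found.append((name, start, start + len(seq), strand, mm))
    return found


def map_read(index: GenomeIndex, read_id: str, seq: str,
             config: MapConfig) -> MapResult:
    """Map one read on both strands, keeping the best mismatch stratum."""
    brute = len(seq) < index.k
    placements = _scan_placements(index, seq, "+", config.max_mismatches, brute)
    placements += _scan_placements(index, revcomp(seq), "-",
                                   config.max_mismatches, brute)
    if not placements:
        return MapResult(read_id, "unmapped")
    best = min(p[4] for p in placements)
    stratum = {p for p in placements if p[4] == best}
    # a palindromic read matches both orientations at one locus; that is a
    # single placement, reported on the forward strand
    stratum = {p for p in stratum
               if p[3] == "+" or (p[0], p[1], p[2], "+", p[4]) not in stratum}
    stratum = sorted(stratum)
    if len(stratum) > config.max_loci:
        return MapResult(read_id, "multimap")
    hits = [AlignmentHit(read_id, n, s, e, st, mm) for n, s, e, st, mm in stratum]
    return MapResult(read_id, "mapped", hits)


def map_reads(reads: Sequence[FastqRecord], index: GenomeIndex,
              config: MapConfig) -> list[MapResult]:
    """Map a collection of reads, caching identical sequences."""
    cache: dict[str, MapResult] = {}
    results = []
    for rec in reads:
        proto = cache.get(rec.seq)
        if proto is None:
            proto = map_read(index, rec.id, rec.seq, config)
            cache[rec.seq] = proto
        hits = [AlignmentHit(rec.id, h.scaffold, h.start, h.end, h.strand,
                             h.mismatches) for h in proto.hits]
        results.append(MapResult(rec.id, proto.status, hits))
    return results


@dataclass
class ReadStack:
    """Reads merged into one genomic window on a scaffold+strand."""

    scaffold: str
    strand: str
    start: int
    end: int
    reads: list[AlignmentHit] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    @property
    def five_prime_counts(self) -> Counter:
        """Per-position counts of read 5' ends (strand-aware)."""
        return Counter(h.start if self.strand == "+" else h.end
                       for h in self.reads)

    def modal_interval(self) -> tuple[int, int]:
        """The most common (start, end) among member reads; ties break to
        the leftmost interval for reproducibility."""
        c = Counter((h.start, h.end) for h in self.reads)
        top = max(c.values())
        return min(iv for iv, n in c.items() if n == top)


def build_stacks(hits: Iterable[AlignmentHit], merge_gap: int = 30) -> list[ReadStack]:
    """Chain hits within ``merge_gap`` nt on one scaffold+strand into stacks.

    Order-invariant: hits are sorted internally.  Every multi-locus read
    contributes to the stack at each of its retained placements.
    """
    groups: dict[tuple[str, str], list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        groups[(h.scaffold, h.strand)].append(h)
    stacks: list[ReadStack] = []
    for (scaf, strand), hs in sorted(groups.items()):
        hs.sort(key=lambda h: (h.start, h.end, h.read_id))
        cur: ReadStack | None = None
        for h in hs:
            if cur is not None and h.start - cur.end <= merge_gap:
                cur.end = max(cur.end, h.end)
                cur.reads.append(h)
            else:
                cur = ReadStack(scaf, strand, h.start, h.end, [h])
                stacks.append(cur)
    return stacks


def mapped_length_histogram(hits: Iterable[AlignmentHit]
                            ) -> tuple[dict[int, int], list[int]]:
    """Histogram of mapped read lengths (each read counted once) and its
    mode(s); ties report every tied length."""
    seen: dict[str, int] = {}
    for h in hits:
        seen.setdefault(h.read_id, h.end - h.start)
    hist = dict(sorted(Counter(seen.values()).items()))
    if not hist:
        return {}, []
    top = max(hist.values())
    return hist, [length for length, n in hist.items() if n == top]
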