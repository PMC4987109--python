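"""Alignment-based paralog/ortholog search and family copy numbers.

The search mechanizes what a manual curation workflow does: find candidate
loci by sequence similarity under short-nucleotide scoring (+2/-3, affine
gaps 5/2, 70% identity), then confirm an ortholog only when the alignment
covers at least 90% of one mature arm at the identity gate — mature arms,
not loops, carry the conserved signal.  Confirmed loci are clustered into
families by single-linkage over mature-arm similarity, yielding a
family x species copy-number matrix with absent/single/multicopy classes.

Karlin-Altschul statistics provide optional E-value gating for genome-scale
scans; lambda is solved exactly from the scoring scheme, K is a configured
heuristic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import exp, log

import numpy as np
import pandas as pd

from mirdup._kernels import sw_affine_align, sw_affine_score
from mirdup.config import AlignParams
from mirdup.mapping import KmerIndex
from mirdup.seqio import revcomp


# ---------------------------------------------------------------------------
# local alignment

@dataclass
class LocalAlignment:
    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    aligned_a: str
    aligned_b: str

    @property
    def columns(self) -> int:
        return len(self.aligned_a)

    @property
    def matches(self) -> int:
        return sum(x == y and x != "-" for x, y in zip(self.aligned_a, self.aligned_b))

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    def column_map(self) -> list[tuple[int | None, int | None, bool]]:
        """Per-column (a_pos, b_pos, is_match); gap side reported as None."""
        out = []
        ai, bi = self.a_start, self.b_start
        for x, y in zip(self.aligned_a, self.aligned_b):
            ap = ai if x != "-" else None
            bp = bi if y != "-" else None
            out.append((ap, bp, x == y and x != "-"))
            ai += x != "-"
            bi += y != "-"
        return out


def local_align(a: str, b: str, params: AlignParams | None = None) -> LocalAlignment:
    """Optimal local alignment under (match, mismatch, affine gap) scoring.

    A gap of length L costs ``gap_open + L * gap_extend``.  The empty
    alignment scores 0 and is returned when nothing scores higher.
    Tie-breaks are fixed (diagonal over gaps, endpoint with the smallest
    (i, j)), so results are reproducible.
    """
    p = params or AlignParams()
    if not a or not b:
        raise ValueError("local_align requires non-empty sequences")
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    ba = np.frombuffer(b.encode(), dtype=np.uint8)
    score, a0, b0, ops = sw_affine_align(aa, ba, p.match, p.mismatch,
                                         p.gap_open, p.gap_extend)
    if score <= 0:
        return LocalAlignment(0, 0, 0, 0, 0, "", "")
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = a0, b0
    for op in ops:
        if op == 0:
            out_a.append(a[i])
            out_b.append(b[j])
            i += 1
            j += 1
        elif op == 1:
            out_a.append(a[i])
            out_b.append("-")
            i += 1
        else:
            out_a.append("-")
            out_b.append(b[j])
            j += 1
    return LocalAlignment(int(score), a0, i, b0, j,
                          "".join(out_a), "".join(out_b))


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics

def karlin_altschul_lambda(match: int, mismatch: int,
                           base_freqs: list[float] | None = None) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s(i, j)) = 1 for lambda > 0.

    ``s(i, j)`` is ``match`` on the diagonal and ``mismatch`` elsewhere.
    Bisection to a bracket width of 1e-12; raises when the expected score
    per aligned pair is non-negative (no positive solution exists).
    """
    p = base_freqs if base_freqs is not None else [0.25] * 4
    if abs(sum(p) - 1.0) > 1e-9 or any(x < 0 for x in p):
        raise ValueError("base_freqs must be a probability vector")
    p_same = sum(x * x for x in p)
    expected = p_same * match + (1 - p_same) * mismatch
    if expected >= 0:
        raise ValueError(
            f"expected score per pair is {expected:g} >= 0; "
            "Karlin-Altschul lambda undefined")

    def g(lam: float) -> float:
        return p_same * exp(lam * match) + (1 - p_same) * exp(lam * mismatch) - 1.0

    hi = 1e-3
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e3:  # pragma: no cover
            raise ValueError("no solution bracket found")
    lo = hi / 2.0 if g(hi / 2.0) > 0 else 1e-12
    lo = 1e-12
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    return 0.5 * (lo + hi)


def evalue(score: float, m: int, n: int, lam: float, K: float) -> float:
    """Expected number of chance alignments at or above ``score``."""
    return K * m * n * exp(-lam * score)


# ---------------------------------------------------------------------------
# genome search

@dataclass
class QueryHairpin:
    """A precursor query: sequence plus mature-arm intervals (seq-relative)."""

    id: str
    seq: str
    mature5p: tuple[int, int]
    mature3p: tuple[int, int]
    family: str | None = None


@dataclass
class OrthologHit:
    query_id: str
    species: str
    scaffold: str
    start: int
    end: int
    strand: str
    score: int
    identity: float
    alignment: LocalAlignment
    query_columns: list[tuple[int | None, bool]] = field(default_factory=list)
    evalue: float | None = None


class GenomeWordIndex(KmerIndex):
    """Exact-word index used to anchor seed-and-extend genome scans."""

    def __init__(self, genome: dict[str, str], word: int):
        super().__init__(genome, word)

    @property
    def word(self) -> int:
        return self.k


def _seed_windows(index: GenomeWordIndex, qseq: str, pad: int
                  ) -> list[tuple[str, int, int]]:
    w = index.word
    origins: dict[str, list[int]] = {}
    for qpos in range(len(qseq) - w + 1):
        for name, tpos in index.lookup(qseq[qpos:qpos + w]):
            origins.setdefault(name, []).append(tpos - qpos)
    windows = []
    for name, orgs in origins.items():
        orgs.sort()
        lo = hi = orgs[0]
        for o in orgs[1:]:
            if o - hi <= len(qseq):
                hi = o
            else:
                windows.append((name, max(0, lo - pad),
                                min(len(index.genome[name]), hi + len(qseq) + pad)))
                lo = hi = o
        windows.append((name, max(0, lo - pad),
                        min(len(index.genome[name]), hi + len(qseq) + pad)))
    return windows


def search_genome(query: QueryHairpin, genome: dict[str, str],
                  params: AlignParams | None = None, species: str = "",
                  index: GenomeWordIndex | None = None) -> list[OrthologHit]:
    """Seed-and-extend search for a precursor in a genome (both strands).

    Exact ``seed_length`` words anchor candidate windows; each window is
    scored with the affine local-alignment kernel, and windows that can
    clear the identity (and, when enabled, E-value) gates are realigned
    with traceback.  Hits with > 50% reciprocal overlap are deduplicated,
    keeping the higher score.
    """
    p = params or AlignParams()
    if index is None:
        index = GenomeWordIndex(genome, p.seed_length)
    lam = karlin_altschul_lambda(p.match, p.mismatch)
    if p.evalue_max is not None:
        score_min = log(p.ka_K * len(query.seq) * max(index.total, 1)
                        / p.evalue_max) / lam
    else:
        score_min = 1.0
    qarrs = {"+": query.seq, "-": revcomp(query.seq)}
    hits: list[OrthologHit] = []
    for strand, qseq in qarrs.items():
        qa = np.frombuffer(qseq.encode(), dtype=np.uint8)
        for name, ws, we in _seed_windows(index, qseq, pad=p.extend_window // 4):
            wa = np.frombuffer(genome[name][ws:we].encode(), dtype=np.uint8)
            score, _, _ = sw_affine_score(qa, wa, p.match, p.mismatch,
                                          p.gap_open, p.gap_extend)
            if score < score_min:
                continue
            aln = local_align(qseq, genome[name][ws:we], p)
            if aln.identity < p.min_identity:
                continue
            ev = evalue(aln.score, len(query.seq), index.total, lam, p.ka_K)
            if p.evalue_max is not None and ev > p.evalue_max:
                continue
            qcols = []
            for ap, _bp, is_m in aln.column_map():
                if ap is None:
                    qcols.append((None, is_m))
                else:
                    qpos = ap if strand == "+" else len(qseq) - 1 - ap
                    qcols.append((qpos, is_m))
            hits.append(OrthologHit(
                query_id=query.id, species=species, scaffold=name,
                start=ws + aln.b_start, end=ws + aln.b_end, strand=strand,
                score=aln.score, identity=aln.identity, alignment=aln,
                query_columns=qcols, evalue=ev))
    return _dedup_hits(hits)


def _dedup_hits(hits: list[OrthologHit],
                mature_overlap: int | None = None) -> list[OrthologHit]:
    """Collapse hits sharing a locus, keeping the higher score.

    Overlap is judged against the shorter interval so that an arm-only
    alignment collapses onto a full-precursor alignment of the same locus.
    With ``mature_overlap`` set, any two hits sharing at least that many
    bases also collapse: two precursor detections sharing a mature-sized
    stretch are the same locus found with different boundaries, never two
    distinct paralogs.
    """
    hits = sorted(hits, key=lambda h: (-h.score, h.scaffold, h.start))
    kept: list[OrthologHit] = []
    for h in hits:
        redundant = False
        for k in kept:
            if k.scaffold != h.scaffold:
                continue
            ov = max(0, min(k.end, h.end) - max(k.start, h.start))
            if ov > 0.5 * min(k.end - k.start, h.end - h.start):
                redundant = True
                break
            if mature_overlap is not None and ov >= mature_overlap:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return sorted(kept, key=lambda h: (h.scaffold, h.start))


def confirm_ortholog(hit: OrthologHit, query: QueryHairpin,
                     params: AlignParams | None = None) -> bool:
    """True iff the alignment spans most of the precursor and covers
    >= 90% of at least one mature arm at the identity gate within that arm.

    The precursor-span requirement mirrors judging orthology on the whole
    hairpin alignment: a short chance island of high identity over one arm
    does not make an ortholog.
    """
    p = params or AlignParams()
    aligned_q = {qp for qp, _ in hit.query_columns if qp is not None}
    if len(aligned_q) < p.precursor_coverage_min * len(query.seq):
        return False
    for arm in (query.mature5p, query.mature3p):
        s, e = arm
        in_arm = [(qp, m) for qp, m in hit.query_columns
                  if qp is not None and s <= qp < e]
        if not in_arm:
            continue
        coverage = len({qp for qp, _ in in_arm}) / (e - s)
        identity = sum(m for _, m in in_arm) / len(in_arm)
        if coverage >= p.arm_coverage_min and identity >= p.min_identity:
            return True
    return False


# ---------------------------------------------------------------------------
# family clustering and the copy-number matrix

@dataclass
class FamilyLocus:
    """A confirmed miRNA locus entering family clustering."""

    id: str
    species: str
    scaffold: str
    start: int
    end: int
    strand: str
    matures: list[str]
    known_name: str | None = None


def mature_similarity(a: str, b: str, params: AlignParams | None = None) -> float:
    """Identity of the best local alignment, normalized by the longer
    mature — conserved arms must align along (nearly) their full length."""
    p = params or AlignParams()
    aln = local_align(a, b, p)
    return aln.matches / max(len(a), len(b))


def ungapped_similarity(a: str, b: str, min_overlap: int = 10) -> float:
    """Best ungapped match fraction over all relative offsets.

    Mature products of one family differ by substitutions and small 5'-end
    offsets, never by internal indels; a gapped aligner can stitch chance
    fragments of unrelated matures into a deceptively high identity, so
    family clustering uses this stricter measure.
    """
    best = 0
    n, m = len(a), len(b)
    for shift in range(-(m - min_overlap), n - min_overlap + 1):
        matches = sum(
            a[i] == b[i - shift]
            for i in range(max(0, shift), min(n, m + shift)))
        best = max(best, matches)
    return best / max(n, m)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_families(loci: list[FamilyLocus], params: AlignParams | None = None
                     ) -> dict[str, list[FamilyLocus]]:
    """Single-linkage clustering on the mature-similarity graph.

    An edge joins two loci when any pair of their matures reaches the
    identity gate over the longer mature, under ungapped (shift-tolerant)
    comparison — family members differ by substitutions and 5'-end offsets,
    not internal indels.  Family names: a member's known reference name
    when present, else ``novel-<n>`` in order of first genomic coordinate.
    Input order does not affect the partition.
    """
    p = params or AlignParams()
    loci = sorted(loci, key=lambda l: (l.species, l.scaffold, l.start, l.id))
    uf = _UnionFind(len(loci))
    for i, j in itertools.combinations(range(len(loci)), 2):
        if uf.find(i) == uf.find(j):
            continue
        if any(ungapped_similarity(a, b) >= p.min_identity
               for a in loci[i].matures for b in loci[j].matures):
            uf.union(i, j)
    groups: dict[int, list[FamilyLocus]] = {}
    for i, loc in enumerate(loci):
        groups.setdefault(uf.find(i), []).append(loc)
    ordered = sorted(groups.values(),
                     key=lambda g: min((l.species, l.scaffold, l.start) for l in g))
    families: dict[str, list[FamilyLocus]] = {}
    novel = 0
    for members in ordered:
        known = sorted({l.known_name for l in members if l.known_name})
        if known:
            name = known[0]
        else:
            novel += 1
            name = f"novel-{novel}"
        families[name] = sorted(members, key=lambda l: (l.species, l.scaffold, l.start))
    return families


@dataclass
class CopyNumberMatrix:
    """Family x species paralog counts with single/multicopy classes."""

    counts: pd.DataFrame  # families x species, int

    @classmethod
    def from_families(cls, families: dict[str, list[FamilyLocus]],
                      species: list[str] | None = None) -> "CopyNumberMatrix":
        if species is None:
            species = sorted({l.species for mem in families.values() for l in mem})
        data = {
            fam: [sum(l.species == sp for l in members) for sp in species]
            for fam, members in families.items()
        }
        df = pd.DataFrame.from_dict(data, orient="index", columns=species)
        return cls(df.astype(int))

    def classify(self) -> pd.DataFrame:
        """absent (0), single (1) or multicopy (>= 2) per family/species."""
        def cl(n: int) -> str:
            return "absent" if n == 0 else "single" if n == 1 else "multicopy"
        return self.counts.map(cl)

    def multicopy_families(self, species: str) -> list[str]:
        return list(self.counts.index[self.counts[species] >= 2])


def species_copy_number(queries: list[QueryHairpin],
                        genomes: dict[str, dict[str, str]],
                        params: AlignParams | None = None
                        ) -> tuple[CopyNumberMatrix, dict[str, list[OrthologHit]]]:
    """Copy-number matrix from confirmed genome-search hits.

    Every query (grouped by its family label) is searched against every
    genome; confirmed hits are pooled per species and overlapping hits from
    different queries collapse to the single best-scoring locus.
    """
    p = params or AlignParams()
    per_species_hits: dict[str, list[OrthologHit]] = {}
    fam_of_query = {q.id: (q.family or q.id) for q in queries}
    for sp, genome in genomes.items():
        index = GenomeWordIndex(genome, p.seed_length)
        pool: list[OrthologHit] = []
        for q in queries:
            for h in search_genome(q, genome, p, species=sp, index=index):
                if confirm_ortholog(h, q, p):
                    pool.append(h)
        per_species_hits[sp] = _dedup_hits(pool, mature_overlap=16)
    species = sorted(genomes)
    fams = sorted({fam_of_query[q.id] for q in queries})
    counts = pd.DataFrame(0, index=fams, columns=species, dtype=int)
    for sp, hits in per_species_hits.items():
        for h in hits:
            counts.loc[fam_of_query[h.query_id], sp] += 1
    return CopyNumberMatrix(counts), per_species_hits
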