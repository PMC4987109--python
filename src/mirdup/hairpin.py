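"""Candidate precursor excision, folding and hairpin qualification.

Read stacks seed candidate windows (the stack sitting on either arm of a
putative precursor); each window is folded with a Nussinov-style dynamic
program under one of two simplified energy models and retained when it
carries at least 0.2 kcal/mol of predicted stability per nucleotide.
Qualification then checks miRNA-like geometry: the modal read interval (the
putative mature) must sit on one arm, be largely paired, and have its star
partner — offset by the 2-nt Dicer overhang — on the opposite arm.

The folding models deliberately trade thermodynamic realism for an exactly
testable optimum:

* ``pair_count`` maximizes Watson-Crick + GU pairs; energy is
  ``pair_energy`` per pair.
* ``stacking`` minimizes a sum of stack energies, counting a pair only when
  it is stacked directly on the next pair inward.

Both share the nested-structure space with hairpin loops >= ``min_loop``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mirdup._kernels import nussinov_fill, stacking_fill
from mirdup.config import FoldConfig
from mirdup.mapping import ReadStack
from mirdup.seqio import revcomp

_EPS = 1e-9

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def _norm_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _pair_class(a: str, b: str) -> str | None:
    if (a, b) not in _PAIRS:
        return None
    if "G" in (a, b) and "C" in (a, b):
        return "GC"
    if "U" in (a, b) and "A" in (a, b):
        return "AU"
    return "GU"


def _pairable_matrix(seq: str) -> np.ndarray:
    n = len(seq)
    mat = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        for j in range(i + 1, n):
            if (seq[i], seq[j]) in _PAIRS:
                mat[i, j] = 1
    return mat


def structure_pairs(structure: str) -> list[int]:
    """Partner index per position (-1 when unpaired) from dot-bracket."""
    partner = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            partner[i], partner[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return partner


def _traceback_pairs(dp: np.ndarray, pairable: np.ndarray,
                     min_loop: int) -> list[tuple[int, int]]:
    """Recover one optimal pair set; prefers pairing (i,j) over bifurcation
    and the smallest split point on equal score."""
    pairs: list[tuple[int, int]] = []
    todo = [(0, dp.shape[0] - 1)]
    while todo:
        i, j = todo.pop()
        if i >= j or dp[i, j] == 0:
            continue
        if j - i > min_loop and pairable[i, j] and dp[i, j] == dp[i + 1, j - 1] + 1:
            pairs.append((i, j))
            todo.append((i + 1, j - 1))
        elif dp[i, j] == dp[i + 1, j]:
            todo.append((i + 1, j))
        elif dp[i, j] == dp[i, j - 1]:
            todo.append((i, j - 1))
        else:
            for k in range(i + 1, j):
                if dp[i, j] == dp[i, k] + dp[k + 1, j]:
                    todo.append((i, k))
                    todo.append((k + 1, j))
                    break
    return pairs


def _pair_energy_matrix(seq: str, table: dict[str, float]) -> np.ndarray:
    n = len(seq)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cls = _pair_class(seq[i], seq[j])
            if cls is not None:
                mat[i, j] = table[cls]
    return mat


def _traceback_stacking(W: np.ndarray, V: np.ndarray, pairable: np.ndarray,
                        emat: np.ndarray, min_loop: int) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    todo: list[tuple[int, int, bool]] = [(0, W.shape[0] - 1, False)]
    while todo:
        i, j, as_pair = todo.pop()
        if i >= j:
            continue
        if as_pair:
            pairs.append((i, j))
            e = min(emat[i, j], emat[i + 1, j - 1])
            if (j - 1 - (i + 1) > min_loop and pairable[i + 1, j - 1]
                    and abs(V[i, j] - (V[i + 1, j - 1] + e)) < _EPS):
                todo.append((i + 1, j - 1, True))
            else:
                todo.append((i + 1, j - 1, False))
            continue
        if W[i, j] >= -_EPS:
            continue
        if V[i, j] < 1e29 and abs(W[i, j] - V[i, j]) < _EPS:
            todo.append((i, j, True))
        elif abs(W[i, j] - W[i + 1, j]) < _EPS:
            todo.append((i + 1, j, False))
        elif abs(W[i, j] - W[i, j - 1]) < _EPS:
            todo.append((i, j - 1, False))
        else:
            for k in range(i + 1, j):
                if abs(W[i, j] - (W[i, k] + W[k + 1, j])) < _EPS:
                    todo.append((i, k, False))
                    todo.append((k + 1, j, False))
                    break
    return pairs


def fold_nussinov(sequence: str, config: FoldConfig | None = None,
                  forbid_internal: tuple[int, int] | None = None
                  ) -> tuple[str, float]:
    """Fold a sequence; returns (dot-bracket structure, energy in kcal/mol).

    Deterministic and invariant to T/U spelling; N never pairs.  Sequences
    too short to close a loop return the open structure with energy 0.
    ``forbid_internal`` constrains the fold: no base pair may have both
    ends inside the given interval — used to ask for the best structure in
    which a putative mature pairs outward into a duplex rather than onto
    itself.
    """
    config = config or FoldConfig()
    seq = _norm_rna(sequence)
    n = len(seq)
    if n < config.min_loop + 2:
        return "." * n, 0.0
    pairable = _pairable_matrix(seq)
    if forbid_internal is not None:
        lo, hi = max(0, forbid_internal[0]), min(n, forbid_internal[1])
        pairable[lo:hi, lo:hi] = 0
    if config.energy_model == "pair_count":
        dp = nussinov_fill(pairable, config.min_loop)
        pairs = _traceback_pairs(dp, pairable, config.min_loop)
        mfe = config.pair_energy * len(pairs)
    else:
        emat = _pair_energy_matrix(seq, config.stack_energy)
        W, V = stacking_fill(pairable, emat, config.min_loop)
        pairs = _traceback_stacking(W, V, pairable, emat, config.min_loop)
        mfe = float(W[0, n - 1])
    structure = ["."] * n
    for i, j in pairs:
        structure[i], structure[j] = "(", ")"
    return "".join(structure), float(mfe)


@dataclass
class HairpinCandidate:
    """An excised genomic window with fold and (after qualification) the
    mature/star geometry.  ``start``/``end`` are genomic; ``sequence`` is
    transcript-oriented (reverse-complemented for - strand windows) and all
    ``*_interval`` fields are window-relative in transcript orientation."""

    scaffold: str
    start: int
    end: int
    strand: str
    sequence: str
    stack: ReadStack | None = None
    structure: str = ""
    mfe: float = 0.0
    mature_interval: tuple[int, int] | None = None
    star_interval: tuple[int, int] | None = None
    mature_arm: str | None = None
    mature_paired: int = 0
    duplex_energy: float = 0.0
    rejection: str | None = None

    @property
    def mfe_per_nt(self) -> float:
        return self.mfe / len(self.sequence) if self.sequence else 0.0

    def to_window(self, g_start: int, g_end: int) -> tuple[int, int]:
        """Genomic interval -> window-relative, transcript-oriented."""
        if self.strand == "+":
            return g_start - self.start, g_end - self.start
        return self.end - g_end, self.end - g_start

    def to_genomic(self, w_start: int, w_end: int) -> tuple[int, int]:
        if self.strand == "+":
            return self.start + w_start, self.start + w_end
        return self.end - w_end, self.end - w_start


def excise_candidates(stack: ReadStack, genome: dict[str, str],
                      config: FoldConfig | None = None) -> list[HairpinCandidate]:
    """Two candidate windows per stack: the stack on the 5p arm with a 3'
    flank, and on the 3p arm with a 5' flank; windows shorter than a
    minimal hairpin (2 x modal read + min_loop) are skipped."""
    config = config or FoldConfig()
    scaf_len = len(genome[stack.scaffold])
    flank = config.flank
    ms, me = stack.modal_interval()
    if stack.strand == "+":
        windows = [(stack.start, min(stack.end + flank, scaf_len)),
                   (max(stack.start - flank, 0), stack.end)]
    else:
        windows = [(max(stack.start - flank, 0), stack.end),
                   (stack.start, min(stack.end + flank, scaf_len))]
    # a stack wide enough to span both arms is itself the precursor; a
    # third, flank-free window avoids spurious helices into the flanks
    windows.append((max(stack.start - 3, 0), min(stack.end + 3, scaf_len)))
    out = []
    seen = set()
    min_len = 2 * (me - ms) + config.min_loop
    for ws, we in windows:
        if we - ws < min_len or (ws, we) in seen:
            continue
        seen.add((ws, we))
        seq = genome[stack.scaffold][ws:we]
        if stack.strand == "-":
            seq = revcomp(seq)
        out.append(HairpinCandidate(stack.scaffold, ws, we, stack.strand,
                                    seq, stack))
    return out


def energy_filter(candidate: HairpinCandidate, config: FoldConfig) -> bool:
    """Keep candidates with at least |mfe_per_nt_max| kcal/mol of predicted
    stability per nucleotide (mfe / length <= threshold)."""
    return candidate.mfe_per_nt <= config.mfe_per_nt_max


def qualify_hairpin(candidate: HairpinCandidate, stack: ReadStack,
                    config: FoldConfig) -> HairpinCandidate:
    """Assign mature/star geometry or a rejection reason (in place).

    The modal read interval is the putative mature.  Rejections:
    ``loop_overlap`` (the mature pairs with itself, i.e. spans the loop),
    ``underpaired`` (< ``min_mature_paired`` paired bases), ``star_overlap``
    (the star region, partner positions + 2-nt 3' offset, intersects the
    mature), ``outside`` (modal interval not within the window).
    """
    g_ms, g_me = stack.modal_interval()
    ms, me = candidate.to_window(g_ms, g_me)
    n = len(candidate.sequence)
    if ms < 0 or me > n:
        candidate.rejection = "outside"
        return candidate
    partner = structure_pairs(candidate.structure)
    inside = range(ms, me)
    # a mature spanning the loop pairs extensively with itself; one or two
    # internal pairs are tolerated as traceback noise in a degenerate
    # optimum and simply do not count toward either arm
    self_paired = sum(1 for i in inside if ms <= partner[i] < me
                      and partner[i] != -1)
    if self_paired > 4:
        candidate.rejection = "loop_overlap"
        return candidate
    # partition the mature's partners by side; the star is derived from the
    # majority side so that a handful of stray pairs into the flanking
    # sequence does not disqualify an otherwise clean duplex
    left = [partner[i] for i in inside if 0 <= partner[i] < ms]
    right = [partner[i] for i in inside if partner[i] >= me]
    # the pairing threshold counts every paired mature base; the star is
    # derived from the majority side only
    if len(left) + len(right) + self_paired < config.min_mature_paired:
        candidate.rejection = "underpaired"
        return candidate
    partners = sorted(left if len(left) >= len(right) else right)
    if not partners:
        candidate.rejection = "underpaired"
        return candidate
    # the star is the densest run of partner positions no wider than the
    # mature itself (plus a little slack); stray pairs to loop-adjacent or
    # flanking bases are not part of the duplex and are ignored
    span = (me - ms) + 4
    best = (0, 0, 0)
    j = 0
    for i in range(len(partners)):
        while partners[i] - partners[j] > span:
            j += 1
        if i - j + 1 > best[0]:
            best = (i - j + 1, j, i)
    cluster = partners[best[1]:best[2] + 1]
    star = (cluster[0], min(cluster[-1] + 1 + 2, n))  # +2 Dicer overhang
    if not (star[1] <= ms or star[0] >= me):
        candidate.rejection = "star_overlap"
        return candidate
    # the unpaired span between mature and star is the hairpin loop: it
    # must exist (>= min_loop) and stay within Dicer's reach
    gap = cluster[0] - me if cluster[0] >= me else ms - (cluster[-1] + 1)
    if gap < config.min_loop:
        candidate.rejection = "no_loop"
        return candidate
    if gap > config.max_duplex_gap:
        candidate.rejection = "loop_too_long"
        return candidate
    candidate.mature_interval = (ms, me)
    candidate.star_interval = star
    candidate.mature_arm = "5p" if ms < star[0] else "3p"
    candidate.mature_paired = len(cluster)
    candidate.duplex_energy = _duplex_stacking_energy(
        candidate.sequence, partner, ms, me, cluster[0], cluster[-1], config)
    candidate.rejection = None
    return candidate


def _duplex_stacking_energy(seq: str, partner: list[int], ms: int, me: int,
                            star_lo: int, star_hi: int,
                            config: FoldConfig) -> float:
    """Stacking energy of the mature-star helix alone (kcal/mol).

    A contiguous duplex stacks nearly every pair; a chance matching against
    unrelated sequence is interrupted by bulges and scores far weaker, so
    this separates the genuine stem from look-alike geometries regardless
    of which global energy model produced the structure.
    """
    rna = _norm_rna(seq)
    total = 0.0
    for i in range(ms, me - 1):
        j = partner[i]
        if j == -1 or not (star_lo <= j <= star_hi):
            continue
        if partner[i + 1] != -1 and partner[i + 1] == j - 1:  # stacked pair
            e1 = config.stack_energy[_pair_class(rna[i], rna[j])]
            e2 = config.stack_energy[_pair_class(rna[i + 1], rna[j - 1])]
            total += min(e1, e2)
    return total


def discover(stacks: list[ReadStack], genome: dict[str, str],
             config: FoldConfig | None = None,
             min_stack_reads: int = 1
             ) -> tuple[list[HairpinCandidate], list[HairpinCandidate]]:
    """Excise, fold, energy-filter and qualify candidates for all stacks.

    Returns (qualified, rejected); at most one qualified candidate is kept
    per stack.  Stacks below ``min_stack_reads`` are skipped — they can
    never clear the downstream read-support criterion, so folding them is
    wasted work.  Every window is folded under both energy models with the
    modal mature constrained to pair outward (the question asked of a
    window is whether a duplex geometry exists, not what the globally
    optimal structure happens to look like): the two simplified models err
    in opposite directions, and the read-support / duplex-stability
    selection picks the geometry the data actually support.
    """
    import dataclasses

    config = config or FoldConfig()
    alt = "pair_count" if config.energy_model == "stacking" else "stacking"
    fallback = dataclasses.replace(config, energy_model=alt,
                                   stack_energy=dict(config.stack_energy))
    qualified, rejected = [], []
    for stack in stacks:
        if stack.n_reads < min_stack_reads:
            continue
        per_stack = []
        for fold_cfg in (config, fallback):
            for cand in excise_candidates(stack, genome, fold_cfg):
                ms, me = cand.to_window(*stack.modal_interval())
                forbid = (ms, me) if 0 <= ms < me <= len(cand.sequence) else None
                cand.structure, cand.mfe = fold_nussinov(
                    cand.sequence, fold_cfg, forbid_internal=forbid)
                if not energy_filter(cand, fold_cfg):
                    cand.rejection = "low_energy"
                    rejected.append(cand)
                    continue
                qualify_hairpin(cand, stack, fold_cfg)
                (per_stack if cand.rejection is None else rejected).append(cand)
        if per_stack:
            # prefer the window whose mature+star geometry explains the
            # most reads (the duplex signature); when support ties (e.g.
            # the star arm has no mapped reads), the genuine stem forms a
            # far more stable contiguous duplex than a chance flank helix
            per_stack.sort(key=lambda c: (-_duplex_support(c, stack),
                                          c.duplex_energy,
                                          c.mfe_per_nt, c.start))
            qualified.append(per_stack[0])
            for extra in per_stack[1:]:
                extra.rejection = "redundant_window"
                rejected.append(extra)
    return qualified, rejected


def _duplex_support(candidate: HairpinCandidate, stack: ReadStack) -> int:
    """Number of stack reads lying within the mature or star interval."""
    mature = sorted(candidate.to_genomic(*candidate.mature_interval))
    star = sorted(candidate.to_genomic(*candidate.star_interval))
    n = 0
    for h in stack.reads:
        for lo, hi in (mature, star):
            if min(h.end, hi) - max(h.start, lo) > (h.end - h.start) // 2:
                n += 1
                break
    return n
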