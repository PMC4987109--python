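"""Numba kernels for the dynamic-programming cores.

Only score/fill matrices live here; tracebacks are done in Python where
tie-breaking rules are easier to audit.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True)
def nussinov_fill(pairable: np.ndarray, min_loop: int) -> np.ndarray:
    """Maximum base-pair count over all nested structures of s[i..j].

    ``pairable[i, j]`` marks allowed pairs; hairpin loops must contain at
    least ``min_loop`` unpaired bases (j - i > min_loop).
    """
    n = pairable.shape[0]
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]
            if dp[i, j - 1] > best:
                best = dp[i, j - 1]
            if j - i > min_loop and pairable[i, j]:
                v = dp[i + 1, j - 1] + 1
                if v > best:
                    best = v
            for k in range(i + 1, j):
                v = dp[i, k] + dp[k + 1, j]
                if v > best:
                    best = v
            dp[i, j] = best
    return dp


@numba.njit(cache=True)
def stacking_fill(pairable: np.ndarray, pair_energy: np.ndarray,
                  min_loop: int) -> tuple[np.ndarray, np.ndarray]:
    """Minimum stacking energy over the same nested structure space.

    A pair (i, j) contributes energy only when stacked directly on the pair
    (i+1, j-1); the contribution is the stronger (more negative) of the two
    pairs' class energies, taken from ``pair_energy``.  Returns (W, V):
    W[i, j] is the optimum for s[i..j], V[i, j] the optimum given that
    (i, j) pair with each other (+inf when they cannot).
    """
    n = pairable.shape[0]
    inf = 1e30
    W = np.zeros((n, n))
    V = np.full((n, n), inf)
    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            # V: (i, j) paired
            if j - i > min_loop and pairable[i, j]:
                # inner region without the pair (i+1, j-1)
                inner_np = 0.0
                if j - 1 > i + 1:
                    a = W[i + 2, j - 1]
                    b = W[i + 1, j - 2]
                    inner_np = a if a < b else b
                    for k in range(i + 2, j - 1):
                        v = W[i + 1, k] + W[k + 1, j - 1]
                        if v < inner_np:
                            inner_np = v
                best_v = inner_np
                if V[i + 1, j - 1] < inf / 2:
                    e = pair_energy[i, j]
                    if pair_energy[i + 1, j - 1] < e:
                        e = pair_energy[i + 1, j - 1]
                    v = V[i + 1, j - 1] + e
                    if v < best_v:
                        best_v = v
                V[i, j] = best_v
            # W: unconstrained
            best = W[i + 1, j]
            if W[i, j - 1] < best:
                best = W[i, j - 1]
            if V[i, j] < best:
                best = V[i, j]
            for k in range(i + 1, j):
                v = W[i, k] + W[k + 1, j]
                if v < best:
                    best = v
            W[i, j] = best
    return W, V


@numba.njit(cache=True)
def sw_affine_align(a: np.ndarray, b: np.ndarray, match: int, mismatch: int,
                    gap_open: int, gap_extend: int):
    """Optimal local alignment with affine gaps (cost open + L*extend).

    Returns (score, a_start, b_start, ops) where ops encodes the alignment
    left-to-right: 0 = aligned pair, 1 = gap in b (consumes a), 2 = gap in
    a (consumes b).  Ties prefer the earliest end cell and, during
    traceback, pairing over gaps.
    """
    n, m = a.shape[0], b.shape[0]
    neg = -(10 ** 9)
    M = np.zeros((n + 1, m + 1), dtype=np.int64)
    X = np.full((n + 1, m + 1), neg, dtype=np.int64)
    Y = np.full((n + 1, m + 1), neg, dtype=np.int64)
    best, bi, bj = 0, 0, 0
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            diag = M[i - 1, j - 1]
            if X[i - 1, j - 1] > diag:
                diag = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > diag:
                diag = Y[i - 1, j - 1]
            v = diag + s
            if v < 0:
                v = 0
            M[i, j] = v
            x = M[i - 1, j] - first
            if X[i - 1, j] - gap_extend > x:
                x = X[i - 1, j] - gap_extend
            X[i, j] = x
            y = M[i, j - 1] - first
            if Y[i, j - 1] - gap_extend > y:
                y = Y[i, j - 1] - gap_extend
            Y[i, j] = y
            if v > best:
                best, bi, bj = v, i, j
    ops = np.empty(n + m, dtype=np.int8)
    k = n + m
    if best <= 0:
        return 0, 0, 0, ops[:0]
    i, j, state = bi, bj, 0
    while True:
        if state == 0:
            if M[i, j] == 0:
                break
            s = match if a[i - 1] == b[j - 1] else mismatch
            prev = M[i, j] - s
            k -= 1
            ops[k] = 0
            if prev == M[i - 1, j - 1]:
                state = 0
            elif prev == X[i - 1, j - 1]:
                state = 1
            else:
                state = 2
            i -= 1
            j -= 1
            if state == 0 and M[i, j] == 0:
                break
        elif state == 1:
            k -= 1
            ops[k] = 1
            if X[i, j] == M[i - 1, j] - first:
                state = 0
            i -= 1
        else:
            k -= 1
            ops[k] = 2
            if Y[i, j] == M[i, j - 1] - first:
                state = 0
            j -= 1
    return best, i, j, ops[k:]


@numba.njit(cache=True)
def sw_affine_score(a: np.ndarray, b: np.ndarray, match: int, mismatch: int,
                    gap_open: int, gap_extend: int) -> tuple[int, int, int]:
    """Best local-alignment score under affine gaps (cost open + L*extend).

    Returns (score, end_i, end_j) with 1-based end coordinates into a and b.
    """
    n, m = a.shape[0], b.shape[0]
    neg = -10 ** 9
    M = np.zeros((n + 1, m + 1), dtype=np.int64)
    X = np.full((n + 1, m + 1), neg, dtype=np.int64)
    Y = np.full((n + 1, m + 1), neg, dtype=np.int64)
    best, bi, bj = 0, 0, 0
    first_gap = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            diag = M[i - 1, j - 1]
            if X[i - 1, j - 1] > diag:
                diag = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > diag:
                diag = Y[i - 1, j - 1]
            v = diag + s
            if v < 0:
                v = 0
            M[i, j] = v
            x = M[i - 1, j] - first_gap
            if X[i - 1, j] - gap_extend > x:
                x = X[i - 1, j] - gap_extend
            X[i, j] = x
            y = M[i, j - 1] - first_gap
            if Y[i, j - 1] - gap_extend > y:
                y = Y[i, j - 1] - gap_extend
            Y[i, j] = y
            if v > best:
                best, bi, bj = v, i, j
    return best, bi, bj
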