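"""Independent reference implementations used only to check the package.

Each oracle takes a different computational route from the code it verifies:
structure enumeration instead of the Nussinov recurrence; start-anchored
recursion over gap runs instead of the M/X/Y local-alignment matrices; a
dense-grid ECDF sweep instead of the pooled-points rule.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

RNA_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
             ("G", "U"), ("U", "G")}


def max_pairs_enumeration(seq: str, min_loop: int = 3) -> int:
    """Maximum base-pair count by enumerating nested structures.

    Recursion: position i is unpaired, or pairs with some k > i + min_loop,
    splitting the interval. No memoisation shared with the DP under test.
    """
    s = seq.upper().replace("T", "U")

    def best(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        top = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (s[i], s[k]) in RNA_PAIRS:
                top = max(top, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return top

    return best(0, len(s) - 1)


def best_local_score(a: str, b: str, match: int, mismatch: int,
                     gap_open: int, gap_extend: int) -> int:
    """Best local-alignment score by searching over all alignments.

    An alignment starts and ends on an aligned pair; between pairs it may
    take a gap run of any length L in either sequence at cost
    gap_open + L * gap_extend.  Every start pair (i, j) is tried.
    """
    n, m = len(a), len(b)

    @lru_cache(maxsize=None)
    def from_pair(i: int, j: int) -> int:
        """Best score of an alignment whose first column aligns a[i], b[j]."""
        s = match if a[i] == b[j] else mismatch
        ext = 0
        if i + 1 < n and j + 1 < m:
            ext = max(ext, from_pair(i + 1, j + 1))
            for L in range(1, n - i - 1):
                if i + 1 + L >= n:
                    break
                ext = max(ext, -(gap_open + L * gap_extend)
                          + from_pair(i + 1 + L, j + 1))
            for L in range(1, m - j - 1):
                if j + 1 + L >= m:
                    break
                ext = max(ext, -(gap_open + L * gap_extend)
                          + from_pair(i + 1, j + 1 + L))
        return s + ext

    best = 0
    for i in range(n):
        for j in range(m):
            best = max(best, from_pair(i, j))
    return best


def ks_statistic_grid(x, y, n_grid: int = 20001) -> float:
    """sup |ECDF_x - ECDF_y| by dense-grid evaluation (grid includes the
    sample points, where the step functions change)."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    lo = min(x[0], y[0]) - 1.0
    hi = max(x[-1], y[-1]) + 1.0
    grid = np.unique(np.concatenate([np.linspace(lo, hi, n_grid), x, y]))
    cdf_x = np.searchsorted(x, grid, side="right") / len(x)
    cdf_y = np.searchsorted(y, grid, side="right") / len(y)
    return float(np.max(np.abs(cdf_x - cdf_y)))
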