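"""Full Smith-Waterman oracle used to cross-check the seeded search engine.

Quadratic affine-gap local alignment over the whole dynamic-programming
matrix — independent of the engine's seed-and-extend path.  Locus
enumeration greedily takes the best local alignment, masks a window around
it, and repeats until the best score falls below the threshold.
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sw_best_per_column(q: np.ndarray, s: np.ndarray, match: int, mismatch: int,
                       gap_open: int, gap_extend: int) -> np.ndarray:
    """Best local-alignment score ending at each subject column."""
    n, m = q.size, s.size
    H = np.zeros(m + 1, dtype=np.int64)
    E = np.full(m + 1, -(1 << 30), dtype=np.int64)
    best_col = np.zeros(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        diag = 0
        F = -(1 << 30)
        for j in range(1, m + 1):
            E[j] = max(E[j] + gap_extend, H[j] + gap_open)
            F = max(F + gap_extend, H[j - 1] + gap_open)
            sub = diag + (match if q[i - 1] == s[j - 1] else mismatch)
            diag = H[j]
            h = max(0, sub, E[j], F)
            H[j] = h
            if h > best_col[j]:
                best_col[j] = h
    return best_col[1:]


def sw_loci(q: np.ndarray, s: np.ndarray, threshold: int, match=1, mismatch=-2,
            gap_open=-5, gap_extend=-2, mask_radius=None) -> list[tuple[int, int]]:
    """Greedy enumeration of non-overlapping subject loci scoring >= threshold."""
    s = s.copy()
    radius = mask_radius or q.size
    loci = []
    while True:
        best = sw_best_per_column(q, s, match, mismatch, gap_open, gap_extend)
        j = int(best.argmax())
        score = int(best[j])
        if score < threshold:
            break
        lo, hi = max(0, j - radius), min(s.size, j + radius)
        loci.append((lo, int(score)))
        s[lo:hi] = 4                      # masking code matches nothing
    return sorted(loci)
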