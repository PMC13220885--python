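"""Independent brute-force oracles used across the suite.

These deliberately avoid the package's own algorithms: the aligner oracle
enumerates every gapped local alignment as a monotone matching of positions,
and the Fisher oracle sums exact hypergeometric point masses with integer
arithmetic.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def brute_local_align(
    probe: str, target: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> tuple[int, int, int, int]:
    """Exhaustive local alignment by enumerating monotone position matchings.

    Any gapped local alignment without terminal gaps is a monotone matching
    of k probe positions to k target positions (aligned columns, matched or
    mismatched) plus interior gap columns for the skipped positions.
    Returns (score, matches, target_start, aligned_columns) under the
    tie-break max score, then max matches, then min target start, then min
    columns; the empty alignment scores 0 with start = len(target).
    """
    p = np.frombuffer(probe.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    m, n = len(p), len(t)
    n_code = ord("N")
    best_key = None
    best = (0, 0, n, 0)
    for k in range(1, min(m, n) + 1):
        pis = np.array(list(combinations(range(m), k)))
        tjs = np.array(list(combinations(range(n), k)))
        eq = (p[pis][:, None, :] == t[tjs][None, :, :]) & (p[pis][:, None, :] != n_code)
        matches = eq.sum(axis=2)
        score = matches * match + (k - matches) * mismatch
        probe_gaps = pis[:, -1] - pis[:, 0] + 1 - k
        target_gaps = tjs[:, -1] - tjs[:, 0] + 1 - k
        gaps = probe_gaps[:, None] + target_gaps[None, :]
        score = score + gap * gaps
        cols = k + gaps
        starts = np.broadcast_to(tjs[:, 0][None, :], score.shape)
        key = ((score * 1000 + matches) * 1000 - starts) * 1000 - cols
        idx = np.unravel_index(np.argmax(key), key.shape)
        if best_key is None or key[idx] > best_key:
            best_key = int(key[idx])
            best = (
                int(score[idx]),
                int(matches[idx]),
                int(starts[idx]),
                int(cols[idx]),
            )
    if best[0] <= 0:
        return (0, 0, n, 0)
    return best


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration (exact integers)."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    numerator_obs = comb(row1, a) * comb(row2, c)
    total = 0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        numerator_x = comb(row1, x) * comb(row2, col1 - x)
        if numerator_x <= numerator_obs:
            total += numerator_x
    return total / comb(n, col1)
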