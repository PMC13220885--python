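"""Local sequence alignment for the junction-homology filter.

A desk-scale stand-in for a genome-wide aligner: full Smith-Waterman with a
linear gap penalty, scoring +1/-1/-2 by default.  Identity is defined as
matches divided by *probe* length (a coverage-weighted identity), so a probe
half of which aligns perfectly to a target scores identity 0.5.

Among co-optimal alignments the reported one maximizes the number of matched
columns, then takes the smallest target start; both tie-breaks are resolved
inside the dynamic program, so results are deterministic.  ``N`` never
matches anything (including another ``N``).

The kernel is jitted with numba when available and falls back to the same
pure-Python code otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_MATCH = 1
DEFAULT_MISMATCH = -1
DEFAULT_GAP = -2

_ENCODE = {ord("A"): 0, ord("C"): 1, ord("G"): 2, ord("T"): 3, ord("N"): -1}


@dataclass(frozen=True)
class AlignmentResult:
    score: int
    matches: int
    aligned_columns: int
    identity: float
    target_id: str = ""
    target_start: int = 0  # 0-based start of the alignment in the target
    target_end: int = 0  # 0-based exclusive end


def _encode(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq):
        code = _ENCODE.get(ord(ch))
        if code is None:
            raise ValueError(f"sequence contains non-ACGTN character {ch!r}")
        out[i] = code
    return out


def _sw_kernel(p, t, match, mismatch, gap):  # pragma: no cover - exercised via local_align
    m = p.shape[0]
    n = t.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    Mm = np.zeros((m + 1, n + 1), dtype=np.int64)
    Js = np.zeros((m + 1, n + 1), dtype=np.int64)
    Cl = np.zeros((m + 1, n + 1), dtype=np.int64)
    for j in range(n + 1):
        Js[0, j] = j
    gs = 0
    gm = 0
    gj = n
    gc = 0
    ge = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            ismatch = 1 if (p[i - 1] >= 0 and p[i - 1] == t[j - 1]) else 0
            sub = match if ismatch == 1 else mismatch
            # candidate cells: empty, diagonal, up (gap in target), left (gap in probe)
            bs = 0
            bm = 0
            bj = j
            bc = 0
            qs = H[i - 1, j - 1] + sub
            qm = Mm[i - 1, j - 1] + ismatch
            qj = Js[i - 1, j - 1] if Cl[i - 1, j - 1] > 0 else j - 1
            qc = Cl[i - 1, j - 1] + 1
            if qs > bs or (
                qs == bs
                and (qm > bm or (qm == bm and (qj < bj or (qj == bj and qc < bc))))
            ):
                bs, bm, bj, bc = qs, qm, qj, qc
            qs = H[i - 1, j] + gap
            qm = Mm[i - 1, j]
            qj = Js[i - 1, j]
            qc = Cl[i - 1, j] + 1
            if qs > bs or (
                qs == bs
                and (qm > bm or (qm == bm and (qj < bj or (qj == bj and qc < bc))))
            ):
                bs, bm, bj, bc = qs, qm, qj, qc
            qs = H[i, j - 1] + gap
            qm = Mm[i, j - 1]
            qj = Js[i, j - 1] if Cl[i, j - 1] > 0 else j - 1
            qc = Cl[i, j - 1] + 1
            if qs > bs or (
                qs == bs
                and (qm > bm or (qm == bm and (qj < bj or (qj == bj and qc < bc))))
            ):
                bs, bm, bj, bc = qs, qm, qj, qc
            # the empty alignment is candidate (0, 0, j, 0) above, so bs >= 0;
            # zero-score non-empty prefixes survive to honour the max-matches
            # tie-break among co-optimal alignments
            H[i, j] = bs
            Mm[i, j] = bm
            Js[i, j] = bj
            Cl[i, j] = bc
            if bs > gs or (
                bs == gs
                and bs > 0
                and (bm > gm or (bm == gm and (bj < gj or (bj == gj and bc < gc))))
            ):
                gs, gm, gj, gc, ge = bs, bm, bj, bc, j
    return gs, gm, gj, gc, ge


try:  # pragma: no cover - environment-dependent
    from numba import njit

    _sw = njit(cache=True)(_sw_kernel)
except ImportError:  # pragma: no cover
    _sw = _sw_kernel


def local_align(
    probe: str,
    target: str,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap: int = DEFAULT_GAP,
    target_id: str = "",
) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment of *probe* against *target*.

    Identity is matches / len(probe).  Raises on an empty probe.
    """
    if not probe:
        raise ValueError("empty probe sequence")
    if not target:
        return AlignmentResult(0, 0, 0, 0.0, target_id=target_id)
    p = _encode(probe.upper())
    t = _encode(target.upper())
    score, matches, start, cols, end = _sw(p, t, match, mismatch, gap)
    return AlignmentResult(
        score=int(score),
        matches=int(matches),
        aligned_columns=int(cols),
        identity=matches / len(probe),
        target_id=target_id,
        target_start=int(start),
        target_end=int(end),
    )


def seed_kmer_size(identity_threshold: float, probe_len: int, cap: int = 12) -> int:
    """Pigeonhole k-mer size that a >threshold identity hit must share exactly.

    An alignment with matches > threshold * probe_len has at most
    ``probe_len - min_matches`` probe positions that are not matched, so its
    matched probe positions include a run of at least
    ``ceil(min_matches / (errors + 1))`` consecutive bases, which is an exact
    substring shared with the target (exact under substitution/deletion
    divergence; insertion-rich co-optimal alignments are covered by the cap).
    """
    min_matches = min(probe_len, int(np.floor(identity_threshold * probe_len)) + 1)
    errors = probe_len - min_matches
    k = -(-min_matches // (errors + 1))  # ceil division
    return max(4, min(cap, k))


def shares_kmer(probe: str, target: str, k: int) -> bool:
    """True when *probe* and *target* share any exact N-free k-mer."""
    if len(probe) < k or len(target) < k:
        return True  # too short to prefilter; caller must align
    kmers = {
        probe[i : i + k]
        for i in range(len(probe) - k + 1)
        if "N" not in probe[i : i + k]
    }
    for j in range(len(target) - k + 1):
        if target[j : j + k] in kmers:
            return True
    return False
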