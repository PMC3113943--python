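"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (quadratic scans, full enumeration)
and shares no code with the package's suffix-array / X-drop machinery.
"""

from __future__ import annotations

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices


def brute_suffix_array(text: np.ndarray) -> list[int]:
    """Sort all suffixes of an integer text by direct comparison."""
    return [i for _, i in sorted((tuple(text[i:].tolist()), i) for i in range(len(text)))]


def brute_lcp(text: np.ndarray, i: int, j: int) -> int:
    n = len(text)
    k = 0
    while i + k < n and j + k < n and text[i + k] == text[j + k]:
        k += 1
    return k


def common_substring_exists(a: str, b: str, k: int) -> bool:
    """Naive check for a shared substring of length k."""
    subs = {a[i : i + k] for i in range(len(a) - k + 1) if "x" not in a[i : i + k]}
    return any(b[j : j + k] in subs for j in range(len(b) - k + 1) if "x" not in b[j : j + k])


def brute_mems(query: np.ndarray, subject: np.ndarray, min_len_at) -> set[tuple[int, int, int]]:
    """All maximal common substrings of (query, subject) satisfying the
    per-position minimum length rule.

    ``min_len_at(p)`` gives the required prefix length at query position p.
    A maximal match (qs, ss, L) qualifies if some offset k within it has
    L - k >= min_len_at(qs + k).  Wildcards (codes < 1) never match.
    Returns triples (query_start, subject_start, length).
    """
    nq, ns = len(query), len(subject)
    out = set()
    for d in range(-(nq - 1), ns):  # diagonal = subject_pos - query_pos
        q = max(0, -d)
        while q < nq and q + d < ns:
            s = q + d
            if query[q] >= 1 and query[q] == subject[s]:
                L = 0
                while (
                    q + L < nq
                    and s + L < ns
                    and query[q + L] >= 1
                    and query[q + L] == subject[s + L]
                ):
                    L += 1
                qualifies = any(
                    q + k + 6 <= nq and L - k >= min_len_at(q + k)
                    for k in range(0, max(L - 6 + 1, 0))
                )
                if qualifies:
                    out.add((q, s, L))
                q += L + 1
            else:
                q += 1
    return out


def brute_mismatch_windows(
    query: np.ndarray, subject: np.ndarray, window: int = 10, offsets=(3, 4, 5, 6)
) -> set[tuple[int, int, int, int]]:
    """All (query_pos, subject_pos, mismatch_offset, right-maximal length)
    where the windows differ at exactly one allowed offset."""
    nq, ns = len(query), len(subject)
    out = set()
    for p in range(nq - window + 1):
        w = query[p : p + window]
        if (w < 1).any():
            continue
        for s in range(ns - window + 1):
            v = subject[s : s + window]
            if (v < 1).any():
                continue
            diff = [k for k in range(window) if w[k] != v[k]]
            if len(diff) == 1 and diff[0] in offsets:
                L = window
                while (
                    p + L < nq
                    and s + L < ns
                    and query[p + L] >= 1
                    and query[p + L] == subject[s + L]
                ):
                    L += 1
                out.add((p, s, diff[0], L))
    return out


def brute_best_ungapped(query: str, subject: str, seed, score_fn) -> int:
    """Max score over all ungapped segments containing the seed (xdrop=inf)."""
    qs, ss, L = seed.query_pos, seed.subject_pos, seed.length
    lo = -min(qs, ss)
    hi = min(len(query) - qs, len(subject) - ss)
    col = [score_fn(query[qs + o], subject[ss + o]) for o in range(lo, hi)]
    seed_lo, seed_hi = -lo, -lo + L  # seed columns in `col` coordinates
    best = None
    for a in range(0, seed_lo + 1):
        for b in range(seed_hi, len(col) + 1):
            sc = sum(col[a:b])
            if best is None or sc > best:
                best = sc
    return best


_SW = None


def sw_local_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Smith-Waterman local score, BLOSUM62, gap of length g costing
    open + g*extend — computed by Biopython's PairwiseAligner (an
    implementation independent of the package's extension DP)."""
    global _SW
    if _SW is None:
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score = -(gap_open + gap_extend)
        al.extend_gap_score = -gap_extend
        _SW = al
    return _SW.score(a, b)


def sw_local_path_anchor(a: str, b: str) -> tuple[float, tuple[int, int] | None]:
    """SW score plus one aligned (non-gap) column of an optimal local path,
    usable as an extension anchor; None if the optimum is empty."""
    sw_local_score("A", "A")  # ensure _SW configured
    alns = _SW.align(a, b)
    if len(alns) == 0 or alns.score <= 0:
        return 0.0, None
    aln = alns[0]
    (qblocks, sblocks) = aln.aligned
    if len(qblocks) == 0:
        return float(alns.score), None
    return float(alns.score), (int(qblocks[0][0]), int(sblocks[0][0]))
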