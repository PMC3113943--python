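"""Seed detection in reduced-alphabet space.

Seeds are maximal exact matches (MEMs) between the reduced query and the
reduced database text, of a per-position adaptive minimum length, found by
binary search over the database suffix array.  Extremely frequent words
would otherwise flood the extension stage, so the minimum seed length grows
from 6 up to at most 9 while the expected frequency of the lengthened word
stays above the database median hexamer frequency.

Long seeds (>= 10 symbols) additionally tolerate one mismatch at offset 3,
4, 5 or 6 of the window (patterns OOOXOOOOOO, OOOOXOOOOO, OOOOOXOOOO,
OOOOOOXOOO): the residue at the mismatch slot is replaced by every other
reduced symbol in turn and the modified word is searched exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .db_index import IndexedDatabase

MIN_SEED = 6
MAX_SEED = 9
MISMATCH_SEED_LEN = 10
MISMATCH_OFFSETS = (3, 4, 5, 6)


@dataclass(frozen=True, order=True)
class SeedMatch:
    """An exact (or single-mismatch) reduced-space match.

    ``query_pos``/``subject_pos`` are 0-based; ``subject_pos`` is local to
    ``record``.  ``mismatch_pos`` is the offset of the substituted symbol
    within the seed (None for exact MEMs).
    """

    query_pos: int
    record: int
    subject_pos: int
    length: int
    mismatch_pos: int | None = None

    @property
    def diagonal(self) -> int:
        return self.subject_pos - self.query_pos


def min_seed_length_from_stats(
    hexamer_freq: float,
    median_freq: float,
    compositions: Sequence[float],
    max_extra: int = MAX_SEED - MIN_SEED,
) -> int:
    """Adaptive minimum seed length from word statistics alone.

    Starts at 6.  If the 6-mer frequency exceeds the database median, the
    word is lengthened one symbol at a time — multiplying the expected
    frequency by the composition of each appended symbol — for as long as
    the expectation stays above the median, up to ``max_extra`` extra
    symbols (seed lengths 6-9).  ``compositions`` are the frequencies of the
    symbols that would be appended; running out of them (query end) stops
    the lengthening.
    """
    addlen = 0
    expect = float(hexamer_freq)
    if expect > median_freq:
        while addlen < max_extra and addlen < len(compositions) and expect > median_freq:
            expect *= float(compositions[addlen])
            addlen += 1
    return MIN_SEED + addlen


def min_seed_length(index: IndexedDatabase, reduced_query: np.ndarray, pos: int) -> int:
    """Minimum seed length for the query position ``pos`` (codes array)."""
    q = reduced_query
    if pos + MIN_SEED > len(q):
        raise ValueError("position too close to query end for a 6-mer")
    window = q[pos : pos + MIN_SEED]
    freq = index.hexamer_frequency(window)
    comps = [
        index.symbol_frequency(int(q[pos + MIN_SEED + j]))
        for j in range(min(MAX_SEED - MIN_SEED, len(q) - pos - MIN_SEED))
    ]
    return min_seed_length_from_stats(freq, index.median_hexamer_freq, comps)


# -- suffix array pattern search ------------------------------------------

def _compare(text: np.ndarray, start: int, pattern: np.ndarray) -> int:
    """Lexicographic order of text[start:] vs pattern; 0 if pattern is a prefix."""
    n = len(text)
    for j in range(len(pattern)):
        if start + j >= n:
            return -1
        t = text[start + j]
        p = pattern[j]
        if t < p:
            return -1
        if t > p:
            return 1
    return 0


def sa_range(index: IndexedDatabase, pattern: np.ndarray) -> tuple[int, int]:
    """Half-open suffix-array interval of suffixes starting with ``pattern``."""
    sa = index.suffix_array
    text = index.text
    lo, hi = 0, len(sa)
    while lo < hi:
        mid = (lo + hi) // 2
        if _compare(text, int(sa[mid]), pattern) < 0:
            lo = mid + 1
        else:
            hi = mid
    first = lo
    lo, hi = first, len(sa)
    while lo < hi:
        mid = (lo + hi) // 2
        if _compare(text, int(sa[mid]), pattern) == 0:
            lo = mid + 1
        else:
            hi = mid
    return first, lo


def _extend_maximal(
    text: np.ndarray, q: np.ndarray, qpos: int, tpos: int, length: int
) -> tuple[int, int, int]:
    """Extend an exact match in both directions; wildcards (code<1) block."""
    n = len(text)
    # left
    while (
        qpos > 0
        and tpos > 0
        and q[qpos - 1] >= 1
        and text[tpos - 1] == q[qpos - 1]
    ):
        qpos -= 1
        tpos -= 1
        length += 1
    # right
    while (
        qpos + length < len(q)
        and tpos + length < n
        and q[qpos + length] >= 1
        and text[tpos + length] == q[qpos + length]
    ):
        length += 1
    return qpos, tpos, length


def find_mems(index: IndexedDatabase, reduced_query: np.ndarray) -> list[SeedMatch]:
    """All maximal exact matches satisfying the per-position minimum length.

    For every query position the suffix array yields the database suffixes
    sharing a prefix of the adaptive minimum length; each is grown to its
    maximal extent and duplicates on the same (record, diagonal) — the same
    MEM reached from several starting positions — are suppressed.
    """
    q = reduced_query
    if len(q) < MIN_SEED:
        return []
    text = index.text
    seen: set[tuple[int, int, int]] = set()
    out: list[SeedMatch] = []
    for p in range(len(q) - MIN_SEED + 1):
        if (q[p : p + MIN_SEED] < 1).any():
            continue
        min_len = min_seed_length(index, q, p)
        if p + min_len > len(q):
            continue
        pattern = q[p : p + min_len]
        lo, hi = sa_range(index, pattern)
        for i in range(lo, hi):
            tpos = int(index.suffix_array[i])
            qs, ts, length = _extend_maximal(text, q, p, tpos, min_len)
            key = (qs, ts, length)
            if key in seen:
                continue
            seen.add(key)
            rec, local = index.global_to_local(ts)
            out.append(SeedMatch(qs, rec, local, length))
    out.sort()
    return out


def find_mismatch_seeds(index: IndexedDatabase, reduced_query: np.ndarray) -> list[SeedMatch]:
    """Single-mismatch seeds of length >= 10.

    Every query 10-window gets the symbol at offset 3, 4, 5 or 6 replaced by
    each other reduced symbol in turn; exact occurrences of the modified
    word are looked up in the suffix array and grown rightwards (growing
    leftwards would shift the mismatch offset out of the allowed slots).
    The database symbol at the mismatch offset always differs from the
    query's, so none of these seeds duplicates an exact MEM.
    """
    q = reduced_query
    if len(q) < MISMATCH_SEED_LEN:
        return []
    text = index.text
    size = index.alphabet.size
    seen: set[tuple[int, int, int]] = set()
    out: list[SeedMatch] = []
    for p in range(len(q) - MISMATCH_SEED_LEN + 1):
        window = q[p : p + MISMATCH_SEED_LEN]
        if (window < 1).any():
            continue
        for off in MISMATCH_OFFSETS:
            orig = int(window[off])
            pattern = window.copy()
            for sub in range(1, size + 1):
                if sub == orig:
                    continue
                pattern[off] = sub
                lo, hi = sa_range(index, pattern)
                for i in range(lo, hi):
                    tpos = int(index.suffix_array[i])
                    length = MISMATCH_SEED_LEN
                    while (
                        p + length < len(q)
                        and tpos + length < len(text)
                        and q[p + length] >= 1
                        and text[tpos + length] == q[p + length]
                    ):
                        length += 1
                    key = (p, tpos, off)
                    if key in seen:
                        continue
                    seen.add(key)
                    rec, local = index.global_to_local(tpos)
                    out.append(SeedMatch(p, rec, local, length, mismatch_pos=off))
    out.sort()
    return out
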