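"""Seed extension in the original 20-letter space.

Seeds found in reduced space are extended with BLOSUM62 scores on the
original residues: first an ungapped extension outward from the seed, then
— if the ungapped segment scores above a trigger — an affine-gap dynamic
program outward from the segment's best column, both with X-drop pruning
(an extension direction is abandoned once its running score falls a fixed
amount below the best seen in that direction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from Bio.Align import substitution_matrices

from .seeding import SeedMatch

_NEG = -10 ** 9  # effectively -inf for integer DP


def _load_blosum62() -> tuple[np.ndarray, str]:
    path = resources.files("redsearch.data").joinpath("BLOSUM62")
    with resources.as_file(path) as p:
        mat = substitution_matrices.read(str(p))
    alphabet = str(mat.alphabet)
    arr = np.array(mat, dtype=np.int32)
    ix = alphabet.index("X")
    istar = alphabet.index("*")
    # X must never score positively; '*' (stop codon in translated frames)
    # must be strongly negative against everything so extensions cannot
    # cross a stop with positive score -- including '*' vs '*'.
    arr[ix, :] = np.minimum(arr[ix, :], 0)
    arr[:, ix] = np.minimum(arr[:, ix], 0)
    arr[istar, :] = -4
    arr[:, istar] = -4
    return arr, alphabet


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus gap penalties and extension thresholds.

    A gap of length g costs ``gap_open + g * gap_extend``.  The X-drop and
    trigger thresholds are in raw matrix units; the defaults correspond to
    7 / 15 / 22 bits converted with the matching Karlin lambda (see
    :func:`default_scheme`).
    """

    matrix: np.ndarray = field(repr=False)
    matrix_alphabet: str
    gap_open: int = 11
    gap_extend: int = 1
    xdrop_ungapped: float = 16.0
    xdrop_gapped: float = 39.0
    ungapped_trigger: float = 57.0

    def __post_init__(self) -> None:
        lut = np.full(128, -1, dtype=np.int64)
        for i, ch in enumerate(self.matrix_alphabet):
            lut[ord(ch)] = i
        object.__setattr__(self, "_lut", lut)

    def score(self, a: str, b: str) -> int:
        ia = self._lut[ord(a)]
        ib = self._lut[ord(b)]
        if ia < 0 or ib < 0:
            raise KeyError(f"residue pair {a!r},{b!r} not in scoring matrix")
        return int(self.matrix[ia, ib])

    def encode(self, seq: str) -> np.ndarray:
        """Matrix row indices of a sequence (unknown residues -> X row)."""
        idx = self._lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        idx[idx < 0] = self.matrix_alphabet.index("X")
        return idx


_B62 = None


def default_scheme(**overrides) -> ScoringScheme:
    """BLOSUM62 with BLAST-style gap 11/1 and bit-derived X-drop defaults.

    7 bits (ungapped X-drop, lambda_u=0.3176), 15 bits (gapped X-drop) and
    22 bits (gapped-extension trigger) with lambda_g=0.267 give raw 15.3,
    38.9 and 57.1; the Karlin-Altschul constants assume this parameterization.
    """
    global _B62
    if _B62 is None:
        _B62 = _load_blosum62()
    mat, alpha = _B62
    params = dict(
        matrix=mat,
        matrix_alphabet=alpha,
        gap_open=11,
        gap_extend=1,
        xdrop_ungapped=7 * math.log(2) / 0.3176,
        xdrop_gapped=15 * math.log(2) / 0.267,
        ungapped_trigger=22 * math.log(2) / 0.267,
    )
    params.update(overrides)
    return ScoringScheme(**params)


@dataclass
class Alignment:
    """A scored local alignment; ranges are 0-based half-open."""

    query_range: tuple[int, int]
    subject_range: tuple[int, int]
    raw_score: int
    aligned_query: str
    aligned_subject: str

    @property
    def identities(self) -> int:
        return sum(
            a == b and a != "-"
            for a, b in zip(self.aligned_query, self.aligned_subject)
        )

    @property
    def mismatches(self) -> int:
        return sum(
            a != b and a != "-" and b != "-"
            for a, b in zip(self.aligned_query, self.aligned_subject)
        )

    @property
    def gap_openings(self) -> int:
        n = 0
        prev = None
        for a, b in zip(self.aligned_query, self.aligned_subject):
            kind = "q" if a == "-" else ("s" if b == "-" else None)
            if kind and kind != prev:
                n += 1
            prev = kind
        return n

    @property
    def length(self) -> int:
        return len(self.aligned_query)


def alignment_score(aln: Alignment, scheme: ScoringScheme) -> int:
    """Re-derive the raw score of an alignment from its aligned strings."""
    score = 0
    in_gap = False
    for a, b in zip(aln.aligned_query, aln.aligned_subject):
        if a == "-" or b == "-":
            score -= scheme.gap_extend
            if not in_gap:
                score -= scheme.gap_open
            in_gap = True
        else:
            score += scheme.score(a, b)
            in_gap = False
    return score


# -- ungapped extension ----------------------------------------------------

def _extend_dir_ungapped(scores, start, stop, step, xdrop) -> tuple[int, int]:
    """Best prefix sum along one direction with X-drop; returns (gain, n)."""
    best = 0
    best_n = 0
    run = 0
    n = 0
    i = start
    while i != stop:
        run += scores[i]
        n += 1
        if run > best:
            best, best_n = run, n
        if run < best - xdrop:
            break
        i += step
    return best, best_n


def ungapped_extend(
    query20: str,
    subject20: str,
    seed: SeedMatch,
    scheme: ScoringScheme,
    xdrop: float | None = None,
) -> tuple[Alignment, int]:
    """Extend a seed without gaps; returns the best segment containing it.

    The segment score is seed score + the best left prefix gain + the best
    right suffix gain, each direction abandoned once its running sum drops
    ``xdrop`` below the direction's best.
    """
    if xdrop is None:
        xdrop = scheme.xdrop_ungapped
    qi = scheme.encode(query20)
    si = scheme.encode(subject20)
    qs, ss, L = seed.query_pos, seed.subject_pos, seed.length
    # column scores on the overlap of the two sequences along the diagonal
    lo = -min(qs, ss)
    hi = min(len(query20) - qs, len(subject20) - ss)
    offs = np.arange(lo, hi)
    col = scheme.matrix[qi[qs + offs], si[ss + offs]]
    col_at = {int(o): int(c) for o, c in zip(offs, col)}
    seed_score = int(col[(offs >= 0) & (offs < L)].sum())
    left_gain, left_n = _extend_dir_ungapped(col_at, -1, lo - 1, -1, xdrop)
    right_gain, right_n = _extend_dir_ungapped(col_at, L, hi, 1, xdrop)
    a, b = qs - left_n, qs + L + right_n
    raw = seed_score + left_gain + right_gain
    aln = Alignment(
        query_range=(a, b),
        subject_range=(ss - left_n, ss + L + right_n),
        raw_score=raw,
        aligned_query=query20[a:b],
        aligned_subject=subject20[ss - left_n : ss + L + right_n],
    )
    return aln, raw


def best_anchor(query20: str, subject20: str, aln: Alignment, scheme: ScoringScheme) -> tuple[int, int]:
    """Highest-scoring column of an ungapped segment (leftmost on ties)."""
    qa, qb = aln.query_range
    sa0 = aln.subject_range[0]
    best = None
    best_pos = (qa, sa0)
    for k in range(qb - qa):
        s = scheme.score(query20[qa + k], subject20[sa0 + k])
        if best is None or s > best:
            best = s
            best_pos = (qa + k, sa0 + k)
    return best_pos


# -- gapped extension ------------------------------------------------------

def _dp_halfextend(
    a: str, b: str, scheme: ScoringScheme, xdrop: float
) -> tuple[int, list[tuple[str, str]]]:
    """Affine-gap DP anchored at the origin of ``a`` vs ``b``.

    The alignment must start at (0,0) and may end anywhere (score >= 0, the
    empty extension allowed).  With finite ``xdrop``, match/insertion cells
    more than ``xdrop`` below the best score seen so far are discarded; all
    retained values still correspond to genuine alignments, so the result
    never exceeds the Smith-Waterman optimum.  Rows are computed with numpy
    and the full matrices are kept for traceback.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return 0, []
    ai = scheme.encode(a)
    bi = scheme.encode(b)
    go, ge = scheme.gap_open, scheme.gap_extend
    finite = math.isfinite(xdrop)

    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)   # ends in residue pair
    X = np.full((n + 1, m + 1), _NEG, dtype=np.int64)   # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.int64)   # gap in a (consumes b)
    M[0, 0] = 0
    X[1:, 0] = -(go + np.arange(1, n + 1, dtype=np.int64) * ge)
    Y[0, 1:] = -(go + np.arange(1, m + 1, dtype=np.int64) * ge)
    if finite:
        X[1:, 0][X[1:, 0] < -xdrop] = _NEG
        Y[0, 1:][Y[0, 1:] < -xdrop] = _NEG
    jidx = np.arange(m + 1, dtype=np.int64)

    best = 0
    best_cell = (0, 0)
    for i in range(1, n + 1):
        prev = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1])
        sub = scheme.matrix[ai[i - 1], bi].astype(np.int64)
        mrow = np.where(prev > _NEG // 2, prev + sub, _NEG)
        xrow = np.maximum(M[i - 1, 1:] - go - ge, X[i - 1, 1:] - ge)
        xrow[xrow < _NEG // 2] = _NEG
        rb = int(mrow.max()) if m else _NEG
        if rb > best:
            best = rb
            best_cell = (i, int(mrow.argmax()) + 1)
        if finite:
            cut = best - xdrop
            mrow[mrow < cut] = _NEG
            xrow[xrow < cut] = _NEG
        M[i, 1:] = mrow
        X[i, 1:] = xrow
        # Y from the (pruned) M of this row via the prefix-max identity:
        # Y[i,j] = max_{k<j}(M[i,k] - go - (j-k)*ge)
        t = np.where(M[i] > _NEG // 2, M[i] + jidx * ge, _NEG)
        acc = np.maximum.accumulate(t)
        yrow = acc[:-1] - go - jidx[1:] * ge
        yrow[acc[:-1] < _NEG // 2] = _NEG
        Y[i, 1:] = np.maximum(Y[i, 1:], yrow)
        if finite and mrow.max() <= _NEG // 2 and xrow.max() <= _NEG // 2:
            break

    # traceback from the best end (always in M, or the empty extension)
    cols: list[tuple[str, str]] = []
    i, j = best_cell
    state = "M" if best_cell != (0, 0) else None
    while (i, j) != (0, 0):
        if state == "M":
            cols.append((a[i - 1], b[j - 1]))
            pm, px, py = M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]
            top = max(pm, px, py)
            state = "M" if top == pm else ("X" if top == px else "Y")
            i, j = i - 1, j - 1
        elif state == "X":
            cols.append((a[i - 1], "-"))
            state = "X" if (i > 1 and X[i, j] == X[i - 1, j] - ge) else "M"
            i -= 1
        else:
            cols.append(("-", b[j - 1]))
            state = "Y" if (j > 1 and Y[i, j] == Y[i, j - 1] - ge) else "M"
            j -= 1
    cols.reverse()
    return int(best), cols


def gapped_extend(
    query20: str,
    subject20: str,
    anchor: tuple[int, int],
    scheme: ScoringScheme,
    xdrop: float | None = None,
) -> Alignment:
    """Affine-gap X-drop extension outward from an aligned anchor pair.

    Two half-extensions run from the anchor column: rightward on the
    suffixes and leftward on the reversed prefixes; the tracebacks are
    concatenated through the anchor.  With ``xdrop=inf`` and an anchor on
    the optimal local path this equals the Smith-Waterman local optimum.
    """
    if xdrop is None:
        xdrop = scheme.xdrop_gapped
    qa, sa0 = anchor
    anchor_score = scheme.score(query20[qa], subject20[sa0])
    right_score, right_cols = _dp_halfextend(
        query20[qa + 1 :], subject20[sa0 + 1 :], scheme, xdrop
    )
    left_score, left_cols_rev = _dp_halfextend(
        query20[:qa][::-1], subject20[:sa0][::-1], scheme, xdrop
    )
    cols = (
        [(a, b) for a, b in reversed(left_cols_rev)]
        + [(query20[qa], subject20[sa0])]
        + right_cols
    )
    aq = "".join(c[0] for c in cols)
    asub = "".join(c[1] for c in cols)
    q_used = sum(c[0] != "-" for c in cols)
    s_used = sum(c[1] != "-" for c in cols)
    q_left = sum(c[0] != "-" for c in left_cols_rev)
    s_left = sum(c[1] != "-" for c in left_cols_rev)
    qstart = qa - q_left
    sstart = sa0 - s_left
    return Alignment(
        query_range=(qstart, qstart + q_used),
        subject_range=(sstart, sstart + s_used),
        raw_score=int(left_score + anchor_score + right_score),
        aligned_query=aq,
        aligned_subject=asub,
    )
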