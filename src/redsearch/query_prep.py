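"""Query preparation: six-frame translation and low-complexity masking.

Nucleotide reads are translated in all six reading frames (three offsets on
each strand, standard genetic code) so they can be searched against a
protein database; each frame keeps an affine coordinate map back to the
read.  Peptides are passed through an entropy-based low-complexity filter
in the spirit of SEG: compositionally biased windows are replaced by the
wildcard X so they can neither seed nor inflate alignment scores, while
reported alignments still display the original residues.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

FRAMES = (1, 2, 3, -1, -2, -3)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(read: str) -> str:
    return read.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class QueryFrame:
    """One translated reading frame of a nucleotide read.

    ``frame`` is +1/+2/+3 (forward offsets 0/1/2) or -1/-2/-3 (the same
    offsets on the reverse complement).  ``peptide`` may contain '*' (stop)
    and X (codon with N).
    """

    read_id: str
    frame: int
    peptide: str
    read_length: int

    @property
    def offset(self) -> int:
        return abs(self.frame) - 1

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"

    def peptide_to_read(self, pep_pos: int) -> int:
        """0-based read position of the first base of the codon for
        ``pep_pos`` (first in translation order, so the highest-numbered
        base of the codon on the minus strand)."""
        if not 0 <= pep_pos < len(self.peptide):
            raise IndexError("peptide position outside frame")
        if self.frame > 0:
            return self.offset + 3 * pep_pos
        return self.read_length - 1 - (self.offset + 3 * pep_pos)

    def read_coords(self, pep_start: int, pep_end: int) -> tuple[int, int]:
        """1-based inclusive read coordinates of peptide [pep_start, pep_end).

        On the minus strand start > end, the translated-search convention.
        """
        if pep_end <= pep_start:
            raise ValueError("empty peptide range")
        if self.frame > 0:
            return (
                self.offset + 3 * pep_start + 1,
                self.offset + 3 * pep_end,
            )
        return (
            self.read_length - self.offset - 3 * pep_start,
            self.read_length - self.offset - 3 * pep_end + 1,
        )


def translate_six_frames(read_id: str, read: str) -> list[QueryFrame]:
    """All six reading frames of a read over {A,C,G,T,N}.

    Stop codons become '*', codons containing N become X.  Reads shorter
    than 3 nt yield no usable frame (logged).
    """
    read = read.upper()
    bad = set(read) - set("ACGTN")
    if bad:
        raise ValueError(f"read {read_id}: non-nucleotide characters {sorted(bad)}")
    if len(read) < 3:
        logger.warning("read %s: length %d < 3, no usable frames", read_id, len(read))
        return []
    frames = []
    rc = revcomp(read)
    for frame in FRAMES:
        src = read if frame > 0 else rc
        off = abs(frame) - 1
        n_codons = (len(src) - off) // 3
        if n_codons == 0:
            continue
        chunk = src[off : off + 3 * n_codons]
        pep = list(str(Seq(chunk).translate()))
        for k in range(n_codons):
            if "N" in chunk[3 * k : 3 * k + 3]:
                pep[k] = "X"
        frames.append(QueryFrame(read_id, frame, "".join(pep), len(read)))
    return frames


def _window_entropy(counts: Counter, size: int) -> float:
    h = 0.0
    for c in counts.values():
        if c:
            p = c / size
            h -= p * math.log2(p)
    return h


def mask_low_complexity(
    peptide: str,
    window: int = 12,
    low_cut: float = 2.2,
    high_cut: float = 2.5,
) -> str:
    """Replace low-entropy runs with X (single-pass SEG-style filter).

    Sliding windows below ``low_cut`` bits of Shannon entropy trigger
    masking and are extended through neighbouring windows below
    ``high_cut``.  Windows already containing X are ignored (they neither
    trigger nor extend) and existing X is preserved, which makes the
    operation idempotent: re-masking masked output changes nothing.
    Masking is meant for the *search* copy of a peptide; callers keep the
    original for display.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    peptide = peptide.upper()
    n = len(peptide)
    w = min(window, n)
    if w < 2:
        return peptide
    # sliding-window Shannon entropy (bits) at each window start
    ent: list[float] = []
    counts = Counter(peptide[:w])
    ent.append(_window_entropy(counts, w))
    for i in range(1, n - w + 1):
        counts[peptide[i - 1]] -= 1
        counts[peptide[i + w - 1]] += 1
        ent.append(_window_entropy(counts, w))
    usable = ["X" not in peptide[i : i + w] for i in range(len(ent))]
    trigger = [u and e < low_cut for u, e in zip(usable, ent)]
    extend = [u and e < high_cut for u, e in zip(usable, ent)]
    masked = [False] * n
    for i, trig in enumerate(trigger):
        if not trig:
            continue
        lo = i
        while lo > 0 and extend[lo - 1]:
            lo -= 1
        hi = i
        while hi + 1 < len(ent) and extend[hi + 1]:
            hi += 1
        for p in range(lo, hi + w):
            masked[p] = True
    return "".join("X" if m else c for c, m in zip(peptide, masked))
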