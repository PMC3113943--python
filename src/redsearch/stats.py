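"""Karlin-Altschul significance statistics.

Local alignment scores follow an extreme-value law: the expected number of
distinct alignments scoring at least S between random sequences of lengths
m and n is E = K m n e^(-lambda S).  The bit score S' = (lambda S - ln K)/ln 2
removes the scale dependence, giving E = m n 2^(-S').  The lambda/K pairs
here are the published BLAST values for BLOSUM62 — gapped with open 11 /
extend 1, and ungapped — together with the relative entropy H used for the
edge-effect length correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from operator import attrgetter
from typing import Iterable, Sequence


@dataclass(frozen=True)
class KarlinParams:
    """lambda (nats per raw unit), K, and relative entropy H (nats/position)."""

    lambda_: float
    K: float
    H: float
    source: str = "gapped"

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or not (0 < self.K < 1):
            raise ValueError("require lambda > 0 and 0 < K < 1")


#: BLOSUM62, gap open 11 / extend 1 (the BLAST defaults the statistics assume).
GAPPED_BLOSUM62 = KarlinParams(lambda_=0.267, K=0.041, H=0.14, source="gapped")
#: BLOSUM62 without gaps.
UNGAPPED_BLOSUM62 = KarlinParams(lambda_=0.3176, K=0.134, H=0.4012, source="ungapped")


def bit_score(raw: float, params: KarlinParams = GAPPED_BLOSUM62) -> float:
    """Normalized score in bits: (lambda*S - ln K) / ln 2."""
    return (params.lambda_ * raw - math.log(params.K)) / math.log(2)


def effective_lengths(
    query_len: int, db_len: int, params: KarlinParams
) -> tuple[float, float]:
    """Edge-corrected search-space lengths.

    An alignment cannot start within one expected HSP length of a sequence
    end; the standard correction subtracts l = ln(K m n)/H from each length,
    floored at 1/K so the space never vanishes.
    """
    ell = math.log(params.K * query_len * db_len) / params.H
    return (
        max(query_len - ell, 1.0 / params.K),
        max(db_len - ell, 1.0 / params.K),
    )


def evalue(
    bits: float,
    query_len: int,
    db_len: int,
    params: KarlinParams = GAPPED_BLOSUM62,
    length_correction: bool = True,
) -> float:
    """Expected chance-hit count: E = m' n' 2^(-bits).

    ``db_len`` is the total residue count of the original 20-aa database;
    ``query_len`` the length of the (translated) peptide actually searched.
    With ``length_correction=False`` the raw m*n search space is used.
    """
    if query_len < 1 or db_len < 1:
        raise ValueError("lengths must be >= 1")
    if length_correction:
        m, n = effective_lengths(query_len, db_len, params)
    else:
        m, n = float(query_len), float(db_len)
    return m * n * math.pow(2.0, -bits)


def evalue_from_raw(
    raw: float,
    query_len: int,
    db_len: int,
    params: KarlinParams = GAPPED_BLOSUM62,
    length_correction: bool = True,
) -> tuple[float, float]:
    """(bit score, E-value) of a raw alignment score."""
    bits = bit_score(raw, params)
    return bits, evalue(bits, query_len, db_len, params, length_correction)


def filter_hits(
    hits: Iterable,
    evalue_cutoff: float = 10.0,
    max_hits: int = 100,
) -> list:
    """Keep hits with E <= cutoff, ranked by (E, -bits, subject id), truncated.

    Hits need ``evalue``, ``bits`` and ``subject_id`` attributes; the
    three-part key is a total order, so the ranking is deterministic.
    """
    if max_hits < 1:
        raise ValueError("max_hits must be >= 1")
    kept = [h for h in hits if h.evalue <= evalue_cutoff]
    kept.sort(key=lambda h: (h.evalue, -h.bits, h.subject_id))
    return kept[:max_hits]
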