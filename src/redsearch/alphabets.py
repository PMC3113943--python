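"""Reduced amino-acid alphabets.

A reduced alphabet partitions the 20 standard amino acids into groups of
chemically similar residues (e.g. murphy.10 merges I/L/V/M into one symbol).
Homologous proteins show higher sequence identity in a reduced alphabet than
in the full 20-letter one, which makes long exact matches between homologs
far more common and therefore makes reduced-alphabet substrings efficient
search seeds.

This module parses grouping strings into :class:`ReducedAlphabet` objects,
rewrites protein sequences into reduced space, and scores candidate alphabets
by *seed coverage* (fraction of homologous pairs sharing at least one exact
seed of a given length) and *seed efficiency* (log10 ratio of homologous to
non-homologous pairs sharing a seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity codes folded into the group of a canonical residue, following
#: common practice: B (Asx) -> D, Z (Glx) -> E, U (Sec) -> C, O (Pyl) -> K.
AMBIGUITY_MAP = {"B": "D", "Z": "E", "U": "C", "O": "K"}

#: Characters reduced to the never-matching wildcard symbol.  X (unknown
#: residue) and '*' (stop, from translated frames) must never create seeds.
WILDCARD_CHARS = ("X", "*")

#: Display character for the never-matching symbol in reduced strings.
WILDCARD_SYMBOL = "x"

#: Integer code of the never-matching symbol in encoded sequences; group
#: symbols are coded 1..size.  Matching routines require codes >= 1.
WILDCARD_CODE = 0


class AlphabetError(ValueError):
    """Raised for malformed grouping strings or unknown residues."""


@dataclass(frozen=True)
class ReducedAlphabet:
    """A total surjective map from the 20 amino acids onto group symbols.

    Parameters
    ----------
    name:
        Registry label, e.g. ``"murphy.10"``.
    groups:
        Ordered tuple of residue strings; each group is represented in
        reduced strings by its first residue letter.
    """

    name: str
    groups: tuple[str, ...]
    symbol_of: dict[str, int] = field(repr=False)

    @property
    def size(self) -> int:
        return len(self.groups)

    @property
    def group_chars(self) -> tuple[str, ...]:
        """Display character of each group (its first listed residue)."""
        return tuple(g[0] for g in self.groups)

    def _code_of(self, ch: str) -> int:
        """Integer code (1-based group index) of one residue character."""
        ch = AMBIGUITY_MAP.get(ch, ch)
        if ch in WILDCARD_CHARS:
            return WILDCARD_CODE
        try:
            return self.symbol_of[ch] + 1
        except KeyError:
            raise AlphabetError(f"unknown residue {ch!r} for alphabet {self.name}")

    def encode(self, seq: str) -> np.ndarray:
        """Encode a 20-aa sequence as int16 group codes (wildcard -> 0)."""
        return np.array([self._code_of(c) for c in seq.upper()], dtype=np.int16)

    def reduce(self, seq: str) -> str:
        """Rewrite ``seq`` in reduced space, one display char per residue.

        Length is preserved; X/'*' (and any residue folding to them) become
        the never-matching wildcard ``'x'``.
        """
        chars = self.group_chars
        out = []
        for c in seq.upper():
            code = self._code_of(c)
            out.append(WILDCARD_SYMBOL if code == WILDCARD_CODE else chars[code - 1])
        return "".join(out)


def parse_alphabet(spec: str, name: str = "custom") -> ReducedAlphabet:
    """Parse a grouping string such as ``"A [KR] [EDNQ] C G H [ILVM] [FYW] P [ST]"``.

    Tokens are whitespace separated; a token is a single residue letter or a
    bracketed run of residues sharing one group symbol.  The groups must be
    pairwise disjoint and jointly cover the 20 standard residues exactly.
    """
    tokens = spec.split()
    if not tokens:
        raise AlphabetError("empty alphabet specification")
    groups: list[str] = []
    for tok in tokens:
        if tok.startswith("[") and tok.endswith("]"):
            members = tok[1:-1]
        else:
            members = tok
        if not members:
            raise AlphabetError(f"empty group token {tok!r}")
        for ch in members:
            if ch not in STANDARD_RESIDUES:
                raise AlphabetError(f"non-standard residue {ch!r} in group {tok!r}")
        groups.append(members)
    symbol_of: dict[str, int] = {}
    for idx, g in enumerate(groups):
        for ch in g:
            if ch in symbol_of:
                raise AlphabetError(f"residue {ch!r} assigned to more than one group")
            symbol_of[ch] = idx
    missing = set(STANDARD_RESIDUES) - set(symbol_of)
    if missing:
        raise AlphabetError(f"groups do not cover residues: {''.join(sorted(missing))}")
    return ReducedAlphabet(name=name, groups=tuple(groups), symbol_of=symbol_of)


def _load_registry() -> dict[str, tuple[int, str]]:
    table = {}
    text = resources.files("redsearch.data").joinpath("alphabets.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, size, grouping = line.split("\t")
        table[name] = (int(size), grouping)
    return table


_REGISTRY: dict[str, tuple[int, str]] | None = None


def available_alphabets() -> list[str]:
    """Names of the alphabets shipped in the registry."""
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _load_registry()
    return list(_REGISTRY)


def get_alphabet(name: str) -> ReducedAlphabet:
    """Load a registered alphabet (e.g. ``murphy.10``, the search default)."""
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _load_registry()
    try:
        size, grouping = _REGISTRY[name]
    except KeyError:
        raise AlphabetError(
            f"unknown alphabet {name!r}; available: {', '.join(_REGISTRY)}"
        )
    alpha = parse_alphabet(grouping, name=name)
    if alpha.size != size:
        raise AlphabetError(f"registry size mismatch for {name}")
    return alpha


@dataclass
class HomologPairSet:
    """Pairs of 20-aa sequences labelled homologous or non-homologous."""

    pairs: list[tuple[str, str]]
    label: str = "homologous"

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if not a or not b:
                raise ValueError("empty sequence in pair set")


def _kmer_set(reduced: str, k: int) -> set[str]:
    # wildcard symbols never participate in seeds
    return {
        reduced[i : i + k]
        for i in range(len(reduced) - k + 1)
        if WILDCARD_SYMBOL not in reduced[i : i + k]
    }


def pair_has_seed(a: str, b: str, alphabet: ReducedAlphabet, seed_len: int) -> bool:
    """True if the two sequences share an exact reduced substring of ``seed_len``."""
    ra, rb = alphabet.reduce(a), alphabet.reduce(b)
    return bool(_kmer_set(ra, seed_len) & _kmer_set(rb, seed_len))


def seed_coverage(pairs: HomologPairSet, alphabet: ReducedAlphabet, seed_len: int) -> float:
    """Fraction of pairs sharing at least one exact reduced seed of ``seed_len``."""
    if seed_len < 1:
        raise ValueError("seed_len must be >= 1")
    if not pairs.pairs:
        raise ValueError("empty pair set")
    hits = sum(pair_has_seed(a, b, alphabet, seed_len) for a, b in pairs.pairs)
    return hits / len(pairs.pairs)


def seed_efficiency(
    hom: HomologPairSet,
    nonhom: HomologPairSet,
    alphabet: ReducedAlphabet,
    seed_len: int,
) -> float:
    """log10 ratio of homologous to non-homologous pairs containing a seed.

    A +1 pseudocount replaces a zero denominator so the statistic stays
    finite on small sets; a zero numerator yields ``-inf``.
    """
    if not hom.pairs or not nonhom.pairs:
        raise ValueError("both pair sets must be non-empty")
    n_hom = sum(pair_has_seed(a, b, alphabet, seed_len) for a, b in hom.pairs)
    n_non = sum(pair_has_seed(a, b, alphabet, seed_len) for a, b in nonhom.pairs)
    if n_hom == 0:
        return -math.inf
    return math.log10(n_hom / (n_non if n_non > 0 else 1))


def evaluate_alphabets(
    hom: HomologPairSet,
    nonhom: HomologPairSet,
    alphabets: Iterable[ReducedAlphabet],
    seed_lengths: Sequence[int] = range(3, 16),
) -> pd.DataFrame:
    """Coverage/efficiency table over alphabets and seed lengths.

    Returns a tidy frame with columns ``alphabet, seed_len, coverage,
    efficiency`` — the screen used to choose a seeding alphabet (coverage
    falls and efficiency typically peaks at intermediate lengths).
    """
    rows = []
    for alpha in alphabets:
        for k in seed_lengths:
            rows.append(
                {
                    "alphabet": alpha.name,
                    "seed_len": k,
                    "coverage": seed_coverage(hom, alpha, k),
                    "efficiency": seed_efficiency(hom, nonhom, alpha, k),
                }
            )
    return pd.DataFrame(rows)
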