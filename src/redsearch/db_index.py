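"""Searchable protein database index.

The database is concatenated into one reduced-alphabet integer text with a
distinct sentinel after every sequence.  Group symbols are coded ``1..k``,
the never-matching wildcard is ``0``, and the sentinel after record ``j`` is
the negative value ``j - n_records`` — distinct and lexicographically below
every symbol, so sentinel suffixes sort first and cross-sequence matches are
impossible.  On top of the text we keep:

* a suffix array over the non-sentinel positions and its LCP array, used to
  enumerate maximal exact matches between a query and all database records;
* a 6-mer (hexamer) frequency table and its median, driving the adaptive
  minimum seed length (frequent words demand longer seeds);
* the reduced-symbol composition of the database, used to extrapolate the
  expected frequency of extended words.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .alphabets import (
    AMBIGUITY_MAP,
    STANDARD_RESIDUES,
    ReducedAlphabet,
    get_alphabet,
    parse_alphabet,
)

logger = logging.getLogger(__name__)

INDEX_MAGIC = b"REDSEARCH-IDX"
INDEX_VERSION = 1

_ALLOWED = set(STANDARD_RESIDUES) | set(AMBIGUITY_MAP) | {"X"}


class IndexError_(ValueError):
    """Raised for unreadable, truncated or incompatible index files."""


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    description: str
    residues: str


def sanitize_residues(raw: str) -> str:
    """Uppercase, strip stops/gaps, and replace unknown characters with X."""
    out = []
    for ch in raw.upper():
        if ch in ("*", "-", "."):
            continue
        out.append(ch if ch in _ALLOWED else "X")
    return "".join(out)


def load_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA into sanitized records; empty records are dropped."""
    records = []
    n_dropped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = sanitize_residues(str(rec.seq))
        if not residues:
            n_dropped += 1
            logger.warning("dropping record %s: empty after sanitization", rec.id)
            continue
        records.append(ProteinRecord(rec.id, rec.description, residues))
    if n_dropped:
        logger.warning("dropped %d empty records", n_dropped)
    if not records and n_dropped == 0:
        raise IndexError_(f"no FASTA records found in {path}")
    return records


def suffix_array(text: np.ndarray) -> np.ndarray:
    """Suffix array of an integer text by prefix doubling (O(n log^2 n))."""
    n = len(text)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    # dense initial ranks
    order = np.argsort(text, kind="stable")
    rank = np.empty(n, dtype=np.int64)
    sorted_vals = text[order]
    rank[order] = np.concatenate(([0], np.cumsum(sorted_vals[1:] != sorted_vals[:-1])))
    k = 1
    while True:
        # secondary key: rank of the suffix k positions later (-1 = past end)
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        pair = np.stack((rank[order], key2[order]))
        changed = (pair[:, 1:] != pair[:, :-1]).any(axis=0)
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.concatenate(([0], np.cumsum(changed)))
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


def lcp_array(text: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Kasai LCP array: lcp[i] = common prefix of suffixes sa[i-1], sa[i]."""
    n = len(sa)
    lcp = np.zeros(n, dtype=np.int64)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and text[i + h] == text[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


@dataclass
class IndexedDatabase:
    """Reduced text plus suffix/LCP arrays and word statistics (see module doc)."""

    records: list[ProteinRecord]
    alphabet: ReducedAlphabet
    text: np.ndarray                    # int16 codes incl. sentinels
    seq_starts: np.ndarray              # global start of each record's residues
    suffix_array: np.ndarray            # non-sentinel positions, lex order
    lcp: np.ndarray                     # lcp[i] for (sa[i-1], sa[i]); lcp[0]=0
    hexamer_keys: np.ndarray            # encoded 6-mers (base size+1), sorted
    hexamer_counts: np.ndarray
    median_hexamer_freq: int
    composition: np.ndarray             # composition[c-1] for codes 1..size
    _rec_of_pos: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self._rec_of_pos is None:
            rec_of = np.full(len(self.text), -1, dtype=np.int64)
            for i, start in enumerate(self.seq_starts):
                rec_of[start : start + len(self.records[i].residues)] = i
            self._rec_of_pos = rec_of

    # -- coordinates -------------------------------------------------------
    @property
    def n_residues(self) -> int:
        """Total residue count of the 20-aa database (statistics length n)."""
        return sum(len(r.residues) for r in self.records)

    def global_to_local(self, pos: int) -> tuple[int, int]:
        rec = int(self._rec_of_pos[pos])
        if rec < 0:
            raise ValueError(f"position {pos} is a sentinel")
        return rec, pos - int(self.seq_starts[rec])

    def local_to_global(self, rec: int, local: int) -> int:
        return int(self.seq_starts[rec]) + local

    # -- word statistics ---------------------------------------------------
    def hexamer_frequency(self, window_codes: np.ndarray) -> int:
        """Occurrence count in the database of one reduced 6-mer (0 if unseen
        or if the window contains a wildcard)."""
        if len(window_codes) != 6 or (window_codes < 1).any():
            return 0
        key = _encode_kmer(window_codes, self.alphabet.size)
        i = np.searchsorted(self.hexamer_keys, key)
        if i < len(self.hexamer_keys) and self.hexamer_keys[i] == key:
            return int(self.hexamer_counts[i])
        return 0

    def symbol_frequency(self, code: int) -> float:
        """Database composition of one reduced symbol (0 for the wildcard)."""
        if code < 1:
            return 0.0
        return float(self.composition[code - 1])

    def encode_query(self, seq20: str) -> np.ndarray:
        return self.alphabet.encode(seq20)


def _encode_kmer(codes: np.ndarray, size: int) -> int:
    base = size + 1
    key = 0
    for c in codes:
        key = key * base + int(c)
    return key


def build_index(records: list[ProteinRecord], alphabet: ReducedAlphabet) -> IndexedDatabase:
    """Build the full searchable index from sanitized records."""
    if not records:
        raise ValueError("cannot index an empty record list")
    n_rec = len(records)
    pieces = []
    seq_starts = np.empty(n_rec, dtype=np.int64)
    pos = 0
    for i, rec in enumerate(records):
        codes = alphabet.encode(rec.residues)
        seq_starts[i] = pos
        sentinel = np.array([i - n_rec], dtype=np.int16)
        pieces.append(codes)
        pieces.append(sentinel)
        pos += len(codes) + 1
    text = np.concatenate(pieces)

    sa_full = suffix_array(text)
    lcp_full = lcp_array(text, sa_full)
    # sentinel values are distinct and smaller than every symbol, so the
    # sentinel suffixes occupy exactly the first n_rec slots of the array
    sa = sa_full[n_rec:].copy()
    lcp = lcp_full[n_rec:].copy()
    if len(lcp):
        lcp[0] = 0

    # hexamer table over windows free of sentinels and wildcards
    keys: dict[int, int] = {}
    n = len(text)
    for i in range(n - 5):
        w = text[i : i + 6]
        if (w >= 1).all():
            k = _encode_kmer(w, alphabet.size)
            keys[k] = keys.get(k, 0) + 1
    if keys:
        hk = np.array(sorted(keys), dtype=np.int64)
        hc = np.array([keys[k] for k in sorted(keys)], dtype=np.int64)
        median = int(np.median(hc))
    else:
        hk = np.empty(0, dtype=np.int64)
        hc = np.empty(0, dtype=np.int64)
        median = 0

    sym = text[text >= 1]
    comp = np.bincount(sym, minlength=alphabet.size + 1)[1:].astype(float)
    total = comp.sum()
    composition = comp / total if total else comp

    return IndexedDatabase(
        records=records,
        alphabet=alphabet,
        text=text,
        seq_starts=seq_starts,
        suffix_array=sa,
        lcp=lcp,
        hexamer_keys=hk,
        hexamer_counts=hc,
        median_hexamer_freq=median,
        composition=composition,
    )


def build_index_from_fasta(path, alphabet: ReducedAlphabet | str = "murphy.10") -> IndexedDatabase:
    if isinstance(alphabet, str):
        alphabet = get_alphabet(alphabet)
    return build_index(load_fasta(path), alphabet)


# -- persistence -----------------------------------------------------------
# Deterministic container: magic, version line, JSON header (sorted keys),
# then raw .npy blocks in a fixed order.  No timestamps, so rebuilding the
# same input yields a byte-identical file.

_ARRAY_FIELDS = (
    "text",
    "seq_starts",
    "suffix_array",
    "lcp",
    "hexamer_keys",
    "hexamer_counts",
    "composition",
)


def save_index(index: IndexedDatabase, path) -> None:
    header = {
        "version": INDEX_VERSION,
        "alphabet_name": index.alphabet.name,
        "alphabet_spec": " ".join(
            g if len(g) == 1 else f"[{g}]" for g in index.alphabet.groups
        ),
        "median_hexamer_freq": index.median_hexamer_freq,
        "records": [[r.id, r.description, r.residues] for r in index.records],
    }
    blob = json.dumps(header, sort_keys=True).encode()
    with open(path, "wb") as fh:
        fh.write(INDEX_MAGIC + b"\n")
        fh.write(len(blob).to_bytes(8, "little"))
        fh.write(blob)
        for name in _ARRAY_FIELDS:
            buf = io.BytesIO()
            np.save(buf, getattr(index, name), allow_pickle=False)
            data = buf.getvalue()
            fh.write(len(data).to_bytes(8, "little"))
            fh.write(data)


def load_index(path) -> IndexedDatabase:
    try:
        with open(path, "rb") as fh:
            magic = fh.read(len(INDEX_MAGIC) + 1)
            if magic != INDEX_MAGIC + b"\n":
                raise IndexError_(f"{path}: not a redsearch index")
            raw = fh.read(8)
            if len(raw) < 8:
                raise IndexError_(f"{path}: truncated index header")
            blob = fh.read(int.from_bytes(raw, "little"))
            header = json.loads(blob)
            if header.get("version") != INDEX_VERSION:
                raise IndexError_(
                    f"{path}: index version {header.get('version')} "
                    f"!= supported {INDEX_VERSION}"
                )
            arrays = {}
            for name in _ARRAY_FIELDS:
                raw = fh.read(8)
                if len(raw) < 8:
                    raise IndexError_(f"{path}: truncated before array {name}")
                size = int.from_bytes(raw, "little")
                data = fh.read(size)
                if len(data) < size:
                    raise IndexError_(f"{path}: truncated array {name}")
                arrays[name] = np.load(io.BytesIO(data), allow_pickle=False)
    except OSError as exc:
        raise IndexError_(f"cannot read index {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise IndexError_(f"{path}: corrupt index header") from exc
    alphabet = parse_alphabet(header["alphabet_spec"], name=header["alphabet_name"])
    records = [ProteinRecord(i, d, s) for i, d, s in header["records"]]
    return IndexedDatabase(
        records=records,
        alphabet=alphabet,
        median_hexamer_freq=int(header["median_hexamer_freq"]),
        **arrays,
    )
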