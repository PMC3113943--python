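"""End-to-end search pipeline: mask -> seed -> extend -> score -> rank.

For each query (each translated frame for nucleotide queries) the pipeline
masks low-complexity runs, encodes the peptide in the index's reduced
alphabet, collects exact MEM seeds and single-mismatch seeds, extends each
surviving seed (ungapped, then gapped above the trigger) on the original
residues, scores the alignments with Karlin-Altschul statistics, and emits
up to ``max_hits`` rows per query in BLAST tabular (m8) form.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields

from . import align as _align
from . import stats as _stats
from .db_index import IndexedDatabase, sanitize_residues
from .query_prep import QueryFrame, mask_low_complexity, translate_six_frames
from .seeding import SeedMatch, find_mems, find_mismatch_seeds
from .stats import GAPPED_BLOSUM62, evalue_from_raw, filter_hits

logger = logging.getLogger(__name__)

_NT_CHARS = set("ACGTN")


@dataclass
class SearchConfig:
    """Tunable search parameters (defaults follow the tool's conventions:
    E-value cutoff 10, up to 100 hits per query, murphy.10 alphabet)."""

    evalue_cutoff: float = 10.0
    max_hits: int = 100
    query_type: str = "auto"          # auto | protein | nucleotide
    alphabet: str = "murphy.10"
    mask: bool = True
    mismatch_seeds: bool = True
    gap_open: int = 11
    gap_extend: int = 1
    xdrop_ungapped_bits: float = 7.0
    xdrop_gapped_bits: float = 15.0
    ungapped_trigger_bits: float = 22.0
    length_correction: bool = True
    log_level: str = "WARNING"
    rng_seed: int = 0                 # reserved for randomized behaviors

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")
        if self.query_type not in ("auto", "protein", "nucleotide"):
            raise ValueError("query_type must be auto|protein|nucleotide")

    def scheme(self) -> _align.ScoringScheme:
        lam_u = _stats.UNGAPPED_BLOSUM62.lambda_
        lam_g = GAPPED_BLOSUM62.lambda_
        return _align.default_scheme(
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
            xdrop_ungapped=self.xdrop_ungapped_bits * math.log(2) / lam_u,
            xdrop_gapped=self.xdrop_gapped_bits * math.log(2) / lam_g,
            ungapped_trigger=self.ungapped_trigger_bits * math.log(2) / lam_g,
        )

    @classmethod
    def from_file(cls, path, **overrides) -> "SearchConfig":
        """key=value config file; explicit overrides win over the file."""
        values: dict = {}
        valid = {f.name: f.type for f in fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, _, val = line.partition("=")
                key, val = key.strip(), val.strip()
                if key not in valid:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                default = getattr(cls(), key)
                if isinstance(default, bool):
                    values[key] = val.lower() in ("1", "true", "yes", "on")
                elif isinstance(default, int):
                    values[key] = int(val)
                elif isinstance(default, float):
                    values[key] = float(val)
                else:
                    values[key] = val
        values.update(overrides)
        return cls(**values)


@dataclass
class Hit:
    """One reported alignment, carrying everything an m8 row needs."""

    query_id: str
    subject_id: str
    pident: float
    length: int
    mismatches: int
    gap_openings: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bits: float
    raw_score: int = 0
    frame: int = 0
    alignment: _align.Alignment | None = field(default=None, repr=False)

    def m8_row(self) -> str:
        return "\t".join(
            [
                self.query_id,
                self.subject_id,
                f"{self.pident:.1f}",
                str(self.length),
                str(self.mismatches),
                str(self.gap_openings),
                str(self.qstart),
                str(self.qend),
                str(self.sstart),
                str(self.send),
                _format_evalue(self.evalue),
                f"{self.bits:.1f}",
            ]
        )


def _format_evalue(e: float) -> str:
    if e == 0:
        return "0.0"
    if e < 1e-2:
        return f"{e:.1e}"
    return f"{e:.2g}"


def looks_nucleotide(seq: str) -> bool:
    return bool(seq) and set(seq.upper()) <= _NT_CHARS


def _overlay_original(aln: _align.Alignment, original_query: str) -> _align.Alignment:
    """Replace masked query residues in the aligned strings by the originals
    (masking steers seeding/scoring only; output shows real residues)."""
    qpos = aln.query_range[0]
    out = []
    for ch in aln.aligned_query:
        if ch == "-":
            out.append(ch)
        else:
            out.append(original_query[qpos])
            qpos += 1
    return _align.Alignment(
        query_range=aln.query_range,
        subject_range=aln.subject_range,
        raw_score=aln.raw_score,
        aligned_query="".join(out),
        aligned_subject=aln.aligned_subject,
    )


def _search_peptide(
    index: IndexedDatabase,
    peptide: str,
    config: SearchConfig,
    scheme: _align.ScoringScheme,
) -> list[tuple[SeedMatch, _align.Alignment]]:
    """Seed and extend one peptide; returns (seed, display alignment) pairs."""
    search_pep = mask_low_complexity(peptide) if config.mask else peptide
    codes = index.encode_query(search_pep)
    seeds = find_mems(index, codes)
    if config.mismatch_seeds:
        seeds += find_mismatch_seeds(index, codes)
    # long seeds first so their alignments can absorb shorter ones
    seeds.sort(key=lambda s: (-s.length, s.record, s.query_pos, s.subject_pos))
    covered: dict[int, list[tuple[int, int, int, int]]] = {}
    results = []
    for seed in seeds:
        regions = covered.get(seed.record, ())
        q0, q1 = seed.query_pos, seed.query_pos + seed.length
        s0, s1 = seed.subject_pos, seed.subject_pos + seed.length
        if any(q0 >= a and q1 <= b and s0 >= c and s1 <= d for a, b, c, d in regions):
            continue
        subject = index.records[seed.record].residues
        ungapped, raw = _align.ungapped_extend(search_pep, subject, seed, scheme)
        if raw >= scheme.ungapped_trigger:
            anchor = _align.best_anchor(search_pep, subject, ungapped, scheme)
            aln = _align.gapped_extend(search_pep, subject, anchor, scheme)
        else:
            aln = ungapped
        if aln.raw_score <= 0:
            continue
        covered.setdefault(seed.record, []).append(
            (aln.query_range[0], aln.query_range[1],
             aln.subject_range[0], aln.subject_range[1])
        )
        results.append((seed, _overlay_original(aln, peptide)))
    return results


def search_record(
    index: IndexedDatabase,
    query_id: str,
    sequence: str,
    config: SearchConfig,
    scheme: _align.ScoringScheme | None = None,
) -> list[Hit]:
    """Search one query record (protein or nucleotide) against the index."""
    if scheme is None:
        scheme = config.scheme()
    qtype = config.query_type
    if qtype == "auto":
        qtype = "nucleotide" if looks_nucleotide(sequence) else "protein"

    tasks: list[tuple[QueryFrame | None, str]] = []
    if qtype == "nucleotide":
        for frame in translate_six_frames(query_id, sequence):
            tasks.append((frame, frame.peptide))
    else:
        tasks.append((None, sanitize_residues(sequence)))

    hits: list[Hit] = []
    db_len = index.n_residues
    for frame, peptide in tasks:
        if len(peptide) < 6:
            continue
        for seed, aln in _search_peptide(index, peptide, config, scheme):
            bits, ev = evalue_from_raw(
                aln.raw_score,
                len(peptide),
                db_len,
                GAPPED_BLOSUM62,
                config.length_correction,
            )
            qs, qe = aln.query_range
            ss, se = aln.subject_range
            if frame is None:
                q1, q2 = qs + 1, qe
            else:
                q1, q2 = frame.read_coords(qs, qe)
            hits.append(
                Hit(
                    query_id=query_id,
                    subject_id=index.records[seed.record].id,
                    pident=100.0 * aln.identities / aln.length,
                    length=aln.length,
                    mismatches=aln.mismatches,
                    gap_openings=aln.gap_openings,
                    qstart=q1,
                    qend=q2,
                    sstart=ss + 1,
                    send=se,
                    evalue=ev,
                    bits=bits,
                    raw_score=aln.raw_score,
                    frame=frame.frame if frame else 0,
                    alignment=aln,
                )
            )
    return filter_hits(hits, config.evalue_cutoff, config.max_hits)


def search_fasta(
    index: IndexedDatabase, query_path, config: SearchConfig | None = None
) -> list[Hit]:
    """Search every record of a FASTA/FASTQ query file; hits in file order."""
    from Bio import SeqIO

    if config is None:
        config = SearchConfig()
    scheme = config.scheme()
    fmt = "fasta"
    with open(query_path) as fh:
        first = fh.read(1)
        if first == "@":
            fmt = "fastq"
    hits: list[Hit] = []
    n_queries = 0
    for rec in SeqIO.parse(str(query_path), fmt):
        n_queries += 1
        hits.extend(search_record(index, rec.id, str(rec.seq), config, scheme))
    logger.info("searched %d queries, %d hits", n_queries, len(hits))
    return hits


def write_m8(hits: list[Hit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(h.m8_row() + "\n")
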