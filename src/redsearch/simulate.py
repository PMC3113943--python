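"""Synthetic data generation: databases, homolog pairs, simulated reads.

Everything here is seedable and bit-reproducible.  The generators emulate
the study conditions the search machinery is evaluated under: random
protein databases, homolog pairs of controlled percent identity (standing
in for curated distant-homolog alignment pairs at ~20-40% identity), and
short nucleotide reads sampled from coding sequences on either strand with
recorded truth for recall scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import default_scheme
from .alphabets import STANDARD_RESIDUES, HomologPairSet
from .db_index import ProteinRecord

_CODONS = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_protein_db(
    n: int,
    length_range: tuple[int, int] = (80, 200),
    composition: dict[str, float] | None = None,
    rng_seed=0,
) -> list[ProteinRecord]:
    """Random protein records with residues drawn i.i.d. from ``composition``
    (uniform over the 20 residues by default)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(rng_seed)
    residues = np.array(list(STANDARD_RESIDUES))
    if composition is None:
        probs = np.full(20, 1 / 20)
    else:
        probs = np.array([composition.get(r, 0.0) for r in STANDARD_RESIDUES])
        probs = probs / probs.sum()
    lo, hi = length_range
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(residues, size=length, p=probs))
        records.append(ProteinRecord(f"prot{i:05d}", f"prot{i:05d} synthetic", seq))
    return records


@dataclass
class MutationModel:
    """Controls for homolog generation.

    ``target_identity`` is the desired fraction of matching aligned columns;
    indels are opened per residue with ``indel_rate`` and their lengths are
    geometric with parameter ``indel_length_p``.  Substitutions are sampled
    either proportional to exp(BLOSUM62 score) over the 19 alternatives
    ("blosum", so synthetic divergence resembles real substitution biases)
    or uniformly ("uniform").
    """

    target_identity: float = 0.3
    indel_rate: float = 0.01
    indel_length_p: float = 0.5
    substitution: str = "blosum"
    tolerance: float = 0.05
    max_retries: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.target_identity <= 1):
            raise ValueError("target_identity must be in (0, 1]")
        if not (0 <= self.indel_rate <= 1):
            raise ValueError("indel_rate must be in [0, 1]")


def _substitution_tables() -> dict[str, tuple[np.ndarray, np.ndarray]]:
    scheme = default_scheme()
    tables = {}
    for a in STANDARD_RESIDUES:
        others = np.array([b for b in STANDARD_RESIDUES if b != a])
        w = np.array([np.exp(scheme.score(a, b)) for b in others], dtype=float)
        tables[a] = (others, w / w.sum())
    return tables


_SUB_TABLES: dict[str, tuple[np.ndarray, np.ndarray]] | None = None


def mutate_homolog(
    protein: str, model: MutationModel, rng_seed=0
) -> tuple[str, float, tuple[str, str]]:
    """Derive a homolog at the model's target identity.

    Returns ``(homolog, realized_identity, (aligned_orig, aligned_homolog))``
    where identity = matching columns / non-gap aligned columns of the
    recorded truth alignment.  Resamples up to ``model.max_retries`` times
    until the realized identity is within ``model.tolerance`` of target.
    """
    if len(protein) < 20:
        raise ValueError("protein too short to mutate (need >= 20 residues)")
    global _SUB_TABLES
    if _SUB_TABLES is None and model.substitution == "blosum":
        _SUB_TABLES = _substitution_tables()
    rng = _rng(rng_seed)
    residues = np.array(list(STANDARD_RESIDUES))
    p_sub = 1.0 - model.target_identity
    for _ in range(model.max_retries):
        a_cols: list[str] = []
        b_cols: list[str] = []
        i = 0
        n = len(protein)
        while i < n:
            ch = protein[i]
            if rng.random() < model.indel_rate:
                glen = int(rng.geometric(model.indel_length_p))
                if rng.random() < 0.5:  # deletion from the homolog
                    for d in range(min(glen, n - i)):
                        a_cols.append(protein[i + d])
                        b_cols.append("-")
                    i += min(glen, n - i)
                    continue
                # insertion into the homolog
                for _g in range(glen):
                    a_cols.append("-")
                    b_cols.append(str(rng.choice(residues)))
            if rng.random() < p_sub:
                if model.substitution == "blosum":
                    others, probs = _SUB_TABLES[ch]
                    sub = str(rng.choice(others, p=probs))
                else:
                    sub = ch
                    while sub == ch:
                        sub = str(rng.choice(residues))
                a_cols.append(ch)
                b_cols.append(sub)
            else:
                a_cols.append(ch)
                b_cols.append(ch)
            i += 1
        aligned_a = "".join(a_cols)
        aligned_b = "".join(b_cols)
        pairs = [
            (x, y) for x, y in zip(aligned_a, aligned_b) if x != "-" and y != "-"
        ]
        identity = sum(x == y for x, y in pairs) / len(pairs)
        if abs(identity - model.target_identity) <= model.tolerance:
            return aligned_b.replace("-", ""), identity, (aligned_a, aligned_b)
    raise RuntimeError(
        f"could not reach identity {model.target_identity:.2f} "
        f"within {model.max_retries} attempts"
    )


def homolog_pair_set(
    n_pairs: int,
    target_identity: float,
    length_range: tuple[int, int] = (80, 200),
    rng_seed=0,
    **model_kwargs,
) -> HomologPairSet:
    """Homologous pairs at a controlled identity (label 'homologous')."""
    rng = _rng(rng_seed)
    model = MutationModel(target_identity=target_identity, **model_kwargs)
    proteins = generate_protein_db(n_pairs, length_range, rng_seed=rng)
    pairs = []
    for rec in proteins:
        hom, _ident, _truth = mutate_homolog(rec.residues, model, rng)
        pairs.append((rec.residues, hom))
    return HomologPairSet(pairs, label="homologous")


def nonhomolog_pair_set(
    n_pairs: int,
    length_range: tuple[int, int] = (80, 200),
    rng_seed=1,
) -> HomologPairSet:
    """Independent random pairs (label 'non-homologous')."""
    recs = generate_protein_db(2 * n_pairs, length_range, rng_seed=rng_seed)
    pairs = [
        (recs[2 * i].residues, recs[2 * i + 1].residues) for i in range(n_pairs)
    ]
    return HomologPairSet(pairs, label="non-homologous")


def reverse_translate(protein: str, rng_seed=0) -> str:
    """A coding sequence for ``protein`` with codons drawn uniformly."""
    rng = _rng(rng_seed)
    return "".join(str(rng.choice(_CODONS[ch])) for ch in protein.upper())


def simulate_reads(
    cds_records: list[tuple[str, str]],
    read_length: int,
    n_reads: int,
    rng_seed=0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Uniformly sampled reads from either strand of the given CDSs.

    ``cds_records`` is a list of (id, dna).  Returns (reads, truth) where
    reads are (read_id, sequence) and truth records the source id, 0-based
    offset on the forward CDS, and strand of every read.
    """
    rng = _rng(rng_seed)
    for cid, dna in cds_records:
        if len(dna) < read_length:
            raise ValueError(f"CDS {cid} shorter than read length")
    reads = []
    truth_rows = []
    from .query_prep import revcomp

    for i in range(n_reads):
        k = int(rng.integers(len(cds_records)))
        cid, dna = cds_records[k]
        offset = int(rng.integers(0, len(dna) - read_length + 1))
        fragment = dna[offset : offset + read_length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            fragment = revcomp(fragment)
        rid = f"read{i:05d}"
        reads.append((rid, fragment))
        truth_rows.append(
            {"read_id": rid, "source_id": cid, "offset": offset, "strand": strand}
        )
    return reads, pd.DataFrame(truth_rows)


def write_fasta(records, path) -> None:
    """Write (id, seq) tuples or ProteinRecords as unwrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, ProteinRecord):
                fh.write(f">{rec.description}\n{rec.residues}\n")
            else:
                rid, seq = rec
                fh.write(f">{rid}\n{seq}\n")
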