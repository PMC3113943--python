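"""Reduced-alphabet parsing, reduction, and the coverage/efficiency screen."""

from __future__ import annotations

import math

import numpy as np
import pytest

from redsearch.alphabets import (
    AlphabetError,
    HomologPairSet,
    available_alphabets,
    get_alphabet,
    parse_alphabet,
    seed_coverage,
    seed_efficiency,
    evaluate_alphabets,
)
from redsearch.simulate import generate_protein_db, homolog_pair_set, nonhomolog_pair_set

from oracles import common_substring_exists

REGISTRY_SIZES = {
    "all.20": 20,
    "dssp.5": 5,
    "dssp.10": 10,
    "gbmr.4": 4,
    "gbmr.10": 10,
    "hsdm.5": 5,
    "sdm.6": 6,
    "murphy.5": 5,
    "murphy.10": 10,
    "td.5": 5,
    "td.10": 10,
}


@pytest.mark.parametrize("name,size", sorted(REGISTRY_SIZES.items()))
def test_registry_alphabets_parse_with_printed_group_counts(name, size):
    alpha = get_alphabet(name)
    assert alpha.size == size
    # groups partition the 20 residues
    merged = "".join(alpha.groups)
    assert sorted(merged) == sorted("ACDEFGHIKLMNPQRSTVWY")


def test_registry_is_complete():
    assert set(available_alphabets()) == set(REGISTRY_SIZES)


def test_murphy10_merges_kr():
    alpha = parse_alphabet("A [KR] [EDNQ] C G H [ILVM] [FYW] P [ST]", "murphy.10")
    assert alpha.size == 10
    assert alpha.symbol_of["K"] == alpha.symbol_of["R"]
    assert alpha.reduce("ILVM") == alpha.reduce("ILVM")[0] * 4


@pytest.mark.parametrize(
    "spec",
    [
        "A [KR]",                      # 18 residues uncovered
        "",                            # empty
        "A A [KR] [EDNQ] C G H [ILVM] [FYW] P [ST]",  # duplicate residue
        "A [KR] [EDNQ] C G H [ILVM] [FYW] P [STJ]",   # non-standard residue
    ],
)
def test_parse_alphabet_rejects_malformed_specs(spec):
    with pytest.raises(AlphabetError):
        parse_alphabet(spec)


def test_reduce_sequence_basics(murphy10, all20):
    assert murphy10.reduce("") == ""
    # all.20 is the identity up to symbol renaming: distinct residues stay distinct
    seq = "ACDEFGHIKLMNPQRSTVWY"
    reduced = all20.reduce(seq)
    assert len(set(reduced)) == 20
    # length preserved, wildcard never matches
    assert murphy10.reduce("AXA*") == f"{murphy10.reduce('A')}x{murphy10.reduce('A')}x"
    # ambiguity codes fold into canonical groups
    assert murphy10.reduce("B") == murphy10.reduce("D")
    assert murphy10.reduce("Z") == murphy10.reduce("E")
    assert murphy10.reduce("U") == murphy10.reduce("C")
    assert murphy10.reduce("O") == murphy10.reduce("K")
    with pytest.raises(AlphabetError):
        murphy10.reduce("A1")


def test_reduce_is_idempotent_in_reduced_space(murphy10):
    seq = "MKVLAWSTPGHIKRMNDEILVMFYW"
    once = murphy10.reduce(seq)
    assert murphy10.reduce(once) == once


def test_reduction_monotonicity_on_random_pairs(murphy10):
    """%identity in reduced space >= %identity on the 20-aa alphabet."""
    rng = np.random.default_rng(5)
    residues = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    for _ in range(200):
        n = int(rng.integers(10, 60))
        a = "".join(rng.choice(residues, n))
        b = "".join(rng.choice(residues, n))
        id20 = sum(x == y for x, y in zip(a, b)) / n
        ra, rb = murphy10.reduce(a), murphy10.reduce(b)
        idr = sum(x == y for x, y in zip(ra, rb)) / n
        assert idr >= id20


def test_seed_coverage_trivial_cases(murphy10):
    identical = HomologPairSet([("MKVLAWSTPGH", "MKVLAWSTPGH")] * 3)
    assert seed_coverage(identical, murphy10, 6) == 1.0
    # A uses only [ILVM]-group residues, B only [KR]-group residues
    disjoint = HomologPairSet([("ILVMILVM", "KRKRKRKR")])
    assert seed_coverage(disjoint, murphy10, 2) == 0.0
    with pytest.raises(ValueError):
        seed_coverage(HomologPairSet([]), murphy10, 6)


def test_seed_coverage_matches_bruteforce_and_is_monotone(murphy10):
    hom = homolog_pair_set(40, 0.30, length_range=(40, 80), rng_seed=11)
    prev = 1.1
    for k in range(3, 16):
        cov = seed_coverage(hom, murphy10, k)
        brute = sum(
            common_substring_exists(murphy10.reduce(a), murphy10.reduce(b), k)
            for a, b in hom.pairs
        ) / len(hom.pairs)
        assert cov == pytest.approx(brute)
        assert cov <= prev + 1e-12
        prev = cov


def test_coverage_under_identity_alphabet_equals_plain_coverage(all20):
    hom = homolog_pair_set(25, 0.5, length_range=(30, 60), rng_seed=3)
    for k in (3, 5, 8):
        cov = seed_coverage(hom, all20, k)
        brute = sum(
            common_substring_exists(a, b, k) for a, b in hom.pairs
        ) / len(hom.pairs)
        assert cov == pytest.approx(brute)


def test_seed_efficiency_symmetric_and_forced_counts(murphy10):
    pairs = homolog_pair_set(20, 0.4, length_range=(30, 50), rng_seed=9)
    assert seed_efficiency(pairs, pairs, murphy10, 5) == 0.0
    hom = HomologPairSet([("MKVLAWSTPGH", "MKVLAWSTPGH")] * 8)
    non = HomologPairSet([("ILVMILVMIL", "KRKRKRKRKR")] * 4, label="non-homologous")
    assert seed_efficiency(hom, non, murphy10, 4) == pytest.approx(math.log10(8))


def test_efficiency_peaks_at_intermediate_seed_lengths(murphy10):
    hom = homolog_pair_set(60, 0.30, length_range=(60, 120), rng_seed=21)
    non = nonhomolog_pair_set(60, length_range=(60, 120), rng_seed=22)
    eff = {k: seed_efficiency(hom, non, murphy10, k) for k in range(3, 13)}
    finite = {k: v for k, v in eff.items() if math.isfinite(v)}
    peak = max(finite, key=finite.get)
    assert 4 <= peak <= 10   # neither the shortest nor the longest seeds win
    assert eff[3] < finite[peak]


def test_evaluate_alphabets_table_shape(murphy10, all20):
    hom = homolog_pair_set(10, 0.4, length_range=(30, 50), rng_seed=1)
    non = nonhomolog_pair_set(10, length_range=(30, 50), rng_seed=2)
    df = evaluate_alphabets(hom, non, [murphy10, all20], seed_lengths=[4, 6])
    assert list(df.columns) == ["alphabet", "seed_len", "coverage", "efficiency"]
    assert len(df) == 4
    assert set(df["alphabet"]) == {"murphy.10", "all.20"}
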