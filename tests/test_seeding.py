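"""Adaptive minimum seed length, MEM enumeration, and mismatch seeds."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from redsearch.db_index import ProteinRecord, build_index
from redsearch.seeding import (
    MAX_SEED,
    MIN_SEED,
    SeedMatch,
    find_mems,
    find_mismatch_seeds,
    min_seed_length,
    min_seed_length_from_stats,
)
from redsearch.simulate import generate_protein_db

from oracles import brute_mems, brute_mismatch_windows


class TestMinSeedLength:
    def test_at_or_below_median_returns_six(self):
        assert min_seed_length_from_stats(176, 176, [0.1, 0.1, 0.1]) == 6
        assert min_seed_length_from_stats(0, 176, [0.5]) == 6

    def test_hand_traced_single_extension(self):
        # 1000 * 0.1 = 100 drops below the median 176 after one extension
        assert min_seed_length_from_stats(1000, 176, [0.1, 0.1, 0.1]) == 7

    def test_cap_at_nine_for_extremely_frequent_words(self):
        assert min_seed_length_from_stats(1e6, 176, [0.99, 0.99, 0.99]) == 9

    def test_query_end_stops_lengthening(self):
        assert min_seed_length_from_stats(1e6, 176, []) == 6
        assert min_seed_length_from_stats(1e6, 176, [0.9]) == 7

    @given(
        freq=st.floats(0, 1e7),
        median=st.floats(1, 1e4),
        comps=st.lists(st.floats(0.001, 0.999), min_size=0, max_size=3),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_always_within_six_to_nine(self, freq, median, comps):
        assert MIN_SEED <= min_seed_length_from_stats(freq, median, comps) <= MAX_SEED

    def test_non_decreasing_in_frequency(self):
        comps = [0.3, 0.3, 0.3]
        lengths = [
            min_seed_length_from_stats(f, 100, comps)
            for f in [0, 50, 100, 150, 500, 5000, 1e6]
        ]
        assert lengths == sorted(lengths)

    def test_index_backed_wrapper(self, small_index):
        q = small_index.encode_query(small_index.records[0].residues)
        for pos in range(len(q) - 6 + 1):
            assert MIN_SEED <= min_seed_length(small_index, q, pos) <= MAX_SEED


def _subject_codes(index, rec):
    start = int(index.seq_starts[rec])
    return index.text[start : start + len(index.records[rec].residues)]


class TestFindMems:
    def test_self_match_covers_full_record(self, small_index):
        rec = 3
        q = _subject_codes(small_index, rec).copy()
        seeds = find_mems(small_index, q)
        full = [s for s in seeds if s.record == rec]
        assert any(
            s.query_pos == 0 and s.subject_pos == 0 and s.length == len(q)
            for s in full
        )

    def test_no_shared_hexamer_means_no_seeds(self, murphy10):
        # database of [ILVM]-group symbols only, query of [KR]-group only
        idx = build_index([ProteinRecord("a", "a", "ILVMILVMILVM")], murphy10)
        q = idx.encode_query("KRKRKRKRKRKR")
        assert find_mems(idx, q) == []

    def test_short_query_yields_nothing(self, small_index):
        assert find_mems(small_index, small_index.encode_query("MKVLA")) == []

    @pytest.mark.parametrize("trial", range(15))
    def test_equals_bruteforce_enumeration(self, trial, murphy10):
        rng = np.random.default_rng(2000 + trial)
        recs = generate_protein_db(int(rng.integers(2, 8)), (20, 60), rng_seed=rng)
        idx = build_index(recs, murphy10)
        qrec = generate_protein_db(1, (20, 50), rng_seed=rng)[0]
        q = idx.encode_query(qrec.residues)

        got = {
            (s.query_pos, s.record, s.subject_pos, s.length)
            for s in find_mems(idx, q)
        }
        expected = set()
        for r in range(len(recs)):
            subj = _subject_codes(idx, r)
            mems = brute_mems(q, subj, lambda p: min_seed_length(idx, q, p))
            expected |= {(qs, r, ss, L) for qs, ss, L in mems}
        assert got == expected

    def test_every_seed_is_a_true_match(self, small_index):
        qrec = generate_protein_db(1, (60, 60), rng_seed=77)[0]
        q = small_index.encode_query(qrec.residues)
        for s in find_mems(small_index, q):
            subj = _subject_codes(small_index, s.record)
            window_q = q[s.query_pos : s.query_pos + s.length]
            window_s = subj[s.subject_pos : s.subject_pos + s.length]
            assert (window_q >= 1).all()
            assert np.array_equal(window_q, window_s)
            assert s.length >= MIN_SEED


class TestMismatchSeeds:
    def test_planted_single_mismatch(self, murphy10):
        base = "MKVLAWSTPGHIKRMNDE"
        idx = build_index([ProteinRecord("a", "a", base)], murphy10)
        q = idx.encode_query(base).copy()
        # flip the symbol at offset 4 of the first 10-window to another group
        q[4] = 1 if q[4] != 1 else 2
        seeds = find_mismatch_seeds(idx, q)
        assert any(
            s.query_pos == 0 and s.mismatch_pos == 4 and s.length >= 10
            for s in seeds
        )

    def test_identical_query_produces_no_mismatch_seeds(self, murphy10):
        base = "MKVLAWSTPGHIKRMNDE"
        idx = build_index([ProteinRecord("a", "a", base)], murphy10)
        q = idx.encode_query(base)
        assert find_mismatch_seeds(idx, q) == []

    @pytest.mark.parametrize("trial", range(10))
    def test_equals_bruteforce_hamming_windows(self, trial, murphy10):
        rng = np.random.default_rng(3000 + trial)
        recs = generate_protein_db(int(rng.integers(2, 6)), (20, 50), rng_seed=rng)
        idx = build_index(recs, murphy10)
        qrec = generate_protein_db(1, (25, 40), rng_seed=rng)[0]
        q = idx.encode_query(qrec.residues)

        got = {
            (s.query_pos, s.record, s.subject_pos, s.mismatch_pos, s.length)
            for s in find_mismatch_seeds(idx, q)
        }
        expected = set()
        for r in range(len(recs)):
            subj = _subject_codes(idx, r)
            for p, s, off, L in brute_mismatch_windows(q, subj):
                expected.add((p, r, s, off, L))
        assert got == expected

    def test_returned_seeds_are_hamming_one_at_allowed_offset(self, small_index):
        qrec = generate_protein_db(1, (80, 80), rng_seed=88)[0]
        q = small_index.encode_query(qrec.residues)
        for s in find_mismatch_seeds(small_index, q):
            subj = _subject_codes(small_index, s.record)
            wq = q[s.query_pos : s.query_pos + s.length]
            ws = subj[s.subject_pos : s.subject_pos + s.length]
            diff = np.flatnonzero(wq != ws)
            assert s.length >= 10
            assert diff.tolist() == [s.mismatch_pos]
            assert s.mismatch_pos in (3, 4, 5, 6)


def test_reduced_seeding_dominates_identity_alphabet(murphy10, all20):
    """Homolog pairs share seeds at least as often in murphy.10 as in all.20."""
    from redsearch.simulate import homolog_pair_set
    from redsearch.alphabets import seed_coverage

    hom = homolog_pair_set(40, 0.35, length_range=(60, 120), rng_seed=55)
    for L in (5, 6, 7, 8):
        assert seed_coverage(hom, murphy10, L) >= seed_coverage(hom, all20, L)


def test_seedmatch_invariants():
    s = SeedMatch(4, 0, 10, 12, mismatch_pos=5)
    assert s.diagonal == 6
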