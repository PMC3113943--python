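"""Ungapped and gapped X-drop extension against exhaustive oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from redsearch.align import (
    alignment_score,
    best_anchor,
    default_scheme,
    gapped_extend,
    ungapped_extend,
)
from redsearch.seeding import SeedMatch
from redsearch.simulate import MutationModel, generate_protein_db, mutate_homolog

from oracles import brute_best_ungapped, sw_local_score


def test_scheme_invariants(scheme):
    assert np.array_equal(scheme.matrix, scheme.matrix.T)
    ix = scheme.matrix_alphabet.index("X")
    istar = scheme.matrix_alphabet.index("*")
    assert (scheme.matrix[ix] <= 0).all()
    assert (scheme.matrix[istar] == -4).all()
    assert scheme.gap_open > 0 and scheme.gap_extend > 0
    assert scheme.score("W", "W") == 11 and scheme.score("A", "A") == 4


class TestUngapped:
    def test_identical_sequences_full_cover(self, scheme):
        q = "MKVLAWSTPGHIKRMNDE"
        aln, raw = ungapped_extend(q, q, SeedMatch(6, 0, 6, 6), scheme)
        assert aln.query_range == (0, len(q))
        assert raw == sum(scheme.score(c, c) for c in q)
        assert aln.identities == len(q)

    def test_seed_at_origin_left_extension_noop(self, scheme):
        q = "MKVLAW"
        s = "MKVLAWYYYY"
        aln, raw = ungapped_extend(q, s, SeedMatch(0, 0, 0, 6), scheme)
        assert aln.query_range[0] == 0 and aln.subject_range[0] == 0

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_exhaustive_segment_oracle(self, trial, scheme):
        rng = np.random.default_rng(4000 + trial)
        a = generate_protein_db(1, (30, 70), rng_seed=rng)[0].residues
        b, _, _ = mutate_homolog(a, MutationModel(0.5, indel_rate=0.0), rng_seed=rng)
        # plant a seed on the main diagonal inside the identical backbone
        L = 6
        pos = int(rng.integers(0, len(a) - L))
        seed = SeedMatch(pos, 0, pos, L)
        _, raw = ungapped_extend(a, b, seed, scheme, xdrop=math.inf)
        assert raw == brute_best_ungapped(a, b, seed, scheme.score)

    def test_finite_xdrop_never_beats_exhaustive(self, scheme):
        rng = np.random.default_rng(47)
        for _ in range(10):
            a = generate_protein_db(1, (40, 60), rng_seed=rng)[0].residues
            b, _, _ = mutate_homolog(a, MutationModel(0.4, indel_rate=0.0), rng_seed=rng)
            seed = SeedMatch(10, 0, 10, 6)
            _, raw = ungapped_extend(a, b, seed, scheme)
            assert raw <= brute_best_ungapped(a, b, seed, scheme.score)


class TestGapped:
    def test_two_residue_insertion_closed_form(self, scheme):
        q = "MKVLAWSTPGHIKRMNDE"
        s = q[:9] + "AG" + q[9:]
        aln = gapped_extend(q, s, (3, 3), scheme, xdrop=math.inf)
        expected = (
            sum(scheme.score(c, c) for c in q)
            - scheme.gap_open
            - 2 * scheme.gap_extend
        )
        assert aln.raw_score == expected
        assert aln.gap_openings == 1
        assert alignment_score(aln, scheme) == aln.raw_score

    def test_identical_sequences_same_as_ungapped(self, scheme):
        q = "MKVLAWSTPGHIKRMNDE"
        aln = gapped_extend(q, q, (8, 8), scheme, xdrop=math.inf)
        assert aln.raw_score == sum(scheme.score(c, c) for c in q)
        assert "-" not in aln.aligned_query

    @pytest.mark.parametrize("trial", range(20))
    def test_best_seed_extension_reaches_smith_waterman(self, trial, scheme):
        rng = np.random.default_rng(5000 + trial)
        a = generate_protein_db(1, (50, 110), rng_seed=rng)[0].residues
        b, _, _ = mutate_homolog(a, MutationModel(0.6, indel_rate=0.02), rng_seed=rng)
        sw = sw_local_score(a, b, scheme.gap_open, scheme.gap_extend)
        best = 0
        for i in range(len(a) - 3):
            j = b.find(a[i : i + 4])
            if j >= 0:
                aln = gapped_extend(a, b, (i, j), scheme, xdrop=math.inf)
                best = max(best, aln.raw_score)
                assert aln.raw_score <= sw
                assert alignment_score(aln, scheme) == aln.raw_score
        assert best == sw

    @pytest.mark.parametrize("trial", range(10))
    def test_finite_xdrop_bounded_by_smith_waterman(self, trial, scheme):
        rng = np.random.default_rng(6000 + trial)
        a = generate_protein_db(1, (40, 90), rng_seed=rng)[0].residues
        b, _, _ = mutate_homolog(a, MutationModel(0.35, indel_rate=0.03), rng_seed=rng)
        sw = sw_local_score(a, b, scheme.gap_open, scheme.gap_extend)
        anchor = (len(a) // 2, min(len(a) // 2, len(b) - 1))
        aln = gapped_extend(a, b, anchor, scheme)   # default finite xdrop
        assert aln.raw_score <= sw
        assert alignment_score(aln, scheme) == aln.raw_score

    def test_extension_respects_sequence_bounds(self, scheme):
        q = "MK"
        s = "MK"
        aln = gapped_extend(q, s, (0, 0), scheme)
        assert 0 <= aln.query_range[0] and aln.query_range[1] <= len(q)
        assert 0 <= aln.subject_range[0] and aln.subject_range[1] <= len(s)

    def test_stop_codon_blocks_extension(self, scheme):
        # '*' scores -4 vs everything, so extension cannot profitably cross it
        q = "MKVLAW*STPGHIKR"
        s = "MKVLAWQSTPGHIKR"
        aln = gapped_extend(q, s, (2, 2), scheme)
        score_cross = alignment_score(aln, scheme)
        assert score_cross == aln.raw_score
        assert scheme.score("*", "Q") == -4 and scheme.score("*", "*") == -4


def test_best_anchor_picks_highest_scoring_column(scheme):
    q = "AAWAA"
    s = "AAWAA"
    from redsearch.align import Alignment

    aln = Alignment((0, 5), (0, 5), 0, q, s)
    assert best_anchor(q, s, aln, scheme) == (2, 2)  # W:W = 11 dominates
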