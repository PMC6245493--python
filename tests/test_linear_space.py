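import numpy as np
import pytest

import oracles
from stagealign import (
    ScoringScheme,
    forward_vectors,
    gotoh_align,
    gotoh_fill,
    linear_align,
    mm_midpoint,
    nw_align,
    reverse_vectors,
    score_alignment,
    sw_align,
)
from stagealign import linear_space, reference
from stagealign.core import WrongKernelError, gamma
from conftest import random_dna


class TestForwardVectors:
    def test_empty_prefix_is_all_gap_row(self, aff51):
        CC, DD = forward_vectors("", "ACGT", aff51)
        assert CC.tolist() == [0] + [-gamma(j, aff51) for j in range(1, 5)]

    def test_full_prefix_reaches_optimal_score(self, aff51, rng):
        a, b = random_dna(rng, 30), random_dna(rng, 25)
        CC, _ = forward_vectors(a, b, aff51)
        assert CC[-1] == gotoh_fill(a, b, aff51, "global").H[-1, -1]

    def test_rows_match_full_matrix(self, aff51, rng):
        for _ in range(20):
            a = random_dna(rng, int(rng.integers(2, 40)))
            b = random_dna(rng, int(rng.integers(1, 40)))
            i_star = int(rng.integers(0, len(a) + 1))
            dp = gotoh_fill(a, b, aff51, "global")
            CC, DD = forward_vectors(a[:i_star], b, aff51)
            assert (CC == dp.H[i_star]).all()
            if i_star >= 1:
                assert (DD[1:] == dp.F[i_star][1:]).all()

    def test_requires_affine(self, lin112):
        with pytest.raises(WrongKernelError):
            forward_vectors("AC", "ACG", lin112)


class TestReverseVectors:
    def test_empty_suffix(self, aff51):
        RR, _ = reverse_vectors("", "ACG", aff51)
        assert RR.tolist() == [0] + [-gamma(x, aff51) for x in range(1, 4)]

    def test_equals_forward_of_reversed(self, aff51, rng):
        a, b = random_dna(rng, 17), random_dna(rng, 23)
        RR, SS = reverse_vectors(a, b, aff51)
        CC, DD = forward_vectors(a[::-1], b[::-1], aff51)
        assert (RR == CC).all() and (SS == DD).all()

    def test_matches_reverse_full_matrix(self, aff51, rng):
        a, b = random_dna(rng, 21), random_dna(rng, 19)
        RR, _ = reverse_vectors(a, b, aff51)
        dp = gotoh_fill(a[::-1], b[::-1], aff51, "global")
        assert (RR == dp.H[len(a)]).all()


class TestMidpoint:
    def test_identical_even_length_splits_on_diagonal(self, aff51):
        a = "ACGTACGTAC"
        assert mm_midpoint(a, a, aff51) == (5, 5)

    def test_achieved_maximum_equals_optimal_score(self, aff51, rng):
        for _ in range(200):
            a = random_dna(rng, int(rng.integers(2, 50)))
            b = random_dna(rng, int(rng.integers(0, 50)))
            _, _, _, achieved, _ = linear_space._match_midpoint(a, b, aff51, None, None)
            assert achieved == gotoh_fill(a, b, aff51, "global").H[-1, -1]

    def test_empty_target_midpoint_at_zero(self, aff51):
        assert mm_midpoint("ACGT", "", aff51) == (2, 0)

    def test_base_case_error(self, aff51):
        with pytest.raises(ValueError):
            mm_midpoint("A", "ACGT", aff51)

    def test_midpoint_on_an_optimal_path(self, aff51, rng):
        """Prefix-optimal + suffix-optimal through the midpoint equals the optimum."""
        for _ in range(25):
            a = random_dna(rng, int(rng.integers(2, 30)))
            b = random_dna(rng, int(rng.integers(1, 30)))
            i, j, in_gap, achieved, _ = linear_space._match_midpoint(
                a, b, aff51, None, None
            )
            opt = gotoh_fill(a, b, aff51, "global").H[-1, -1]
            assert achieved == opt
            if not in_gap:
                # in the match state the two halves are independent:
                # prefix-optimal + suffix-optimal passes through the midpoint
                left = gotoh_fill(a[:i], b[:j], aff51, "global").H[-1, -1]
                right = gotoh_fill(a[i:], b[j:], aff51, "global").H[-1, -1]
                assert left + right == opt
            # the recursion built on that midpoint reaches the optimum
            cols = linear_space.mm_align_segment(a, b, aff51)
            assert oracles.score_columns(cols, aff51) == opt


class TestLinearAlign:
    def test_printed_global_pair(self, lin112, global_pair):
        aln = linear_align(*global_pair, lin112, mode="global")
        assert aln.score == nw_align(*global_pair, lin112).score == 3

    def test_random_affine_matches_quadratic(self, aff51, rng):
        for _ in range(40):
            a = random_dna(rng, int(rng.integers(1, 400)))
            b = random_dna(rng, int(rng.integers(1, 400)))
            aln = linear_align(a, b, aff51, "global", base_case_area=512)
            assert aln.score == gotoh_fill(a, b, aff51, "global").H[-1, -1]
            assert score_alignment(aln, aff51) == aln.score

    def test_local_matches_quadratic(self, lin112, aff51, rng):
        for _ in range(20):
            a = random_dna(rng, int(rng.integers(1, 200)))
            b = random_dna(rng, int(rng.integers(1, 200)))
            assert (
                linear_align(a, b, lin112, "local").score
                == sw_align(a, b, lin112).score
            )
            assert (
                linear_align(a, b, aff51, "local").score
                == gotoh_align(a, b, aff51, "local").score
            )

    def test_huge_base_case_degenerates_to_single_direct_call(
        self, aff51, rng, monkeypatch
    ):
        a, b = random_dna(rng, 60), random_dna(rng, 50)
        calls = []
        orig = reference._run_fill_affine

        def spy(c0, c1, *args):
            calls.append((len(c0), len(c1)))
            return orig(c0, c1, *args)

        monkeypatch.setattr(reference, "_run_fill_affine", spy)
        aln = linear_align(a, b, aff51, "global", base_case_area=60 * 50)
        assert calls == [(60, 50)]
        assert aln == gotoh_align(a, b, aff51, "global")

    def test_no_full_matrix_allocation(self, aff51, rng, monkeypatch):
        """Structural memory contract: every quadratic fill stays within the
        base-case area; everything else runs through O(n) band kernels."""
        a, b = random_dna(rng, 300), random_dna(rng, 280)
        areas = []
        orig = reference._run_fill_affine

        def spy(c0, c1, *args):
            areas.append(len(c0) * len(c1))
            return orig(c0, c1, *args)

        monkeypatch.setattr(reference, "_run_fill_affine", spy)
        linear_align(a, b, aff51, "global", base_case_area=1024)
        assert areas and max(areas) <= 1024

    def test_concatenation_never_produces_gap_gap_columns(self, aff51, rng):
        for _ in range(10):
            a = random_dna(rng, int(rng.integers(2, 120)))
            b = random_dna(rng, int(rng.integers(2, 120)))
            aln = linear_align(a, b, aff51, "global", base_case_area=16)
            assert all(c != ("-", "-") for c in aln.columns)

    def test_subproblem_areas_strictly_decrease(self, aff51, rng, monkeypatch):
        a, b = random_dna(rng, 150), random_dna(rng, 140)
        seen = []
        orig = linear_space.mm_align_segment

        def spy(r0, r1, scheme, start_gap=None, end_gap=None, base_case_area=4096):
            seen.append(len(r0) * len(r1))
            return orig(r0, r1, scheme, start_gap, end_gap, base_case_area)

        monkeypatch.setattr(linear_space, "mm_align_segment", spy)
        spy(a, b, aff51, base_case_area=64)
        # the recursion terminates because subproblem areas strictly shrink
        assert len(seen) > 1
        assert max(seen[1:]) < seen[0] == len(a) * len(b)
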