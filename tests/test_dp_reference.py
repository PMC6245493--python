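import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from stagealign import (
    ScoringScheme,
    enumerate_optimal_local,
    gotoh_align,
    gotoh_fill,
    nw_align,
    nw_fill,
    score_alignment,
    sw_align,
    sw_best,
    sw_fill,
)
from stagealign.core import SizeGuardError, WrongKernelError
from conftest import random_dna

dna = st.text(alphabet="ACGT", min_size=0, max_size=12)
dna1 = st.text(alphabet="ACGT", min_size=1, max_size=12)


class TestNWFill:
    def test_single_cell(self, lin112):
        H = nw_fill("A", "A", lin112).H
        assert H.tolist() == [[0, -2], [-2, 1]]

    def test_empty_target_costs_one_gap_per_residue(self, lin112):
        assert nw_fill("A", "", lin112).H[-1, -1] == -2

    def test_printed_global_pair_matches_plain_dp_oracle(self, lin112, global_pair):
        dp = nw_fill(*global_pair, lin112)
        # value frozen from the independent plain-Python DP oracle
        assert dp.H[-1, -1] == 3
        oracle = oracles.dp_global_linear(*global_pair, lin112)
        assert dp.H.tolist() == oracle

    def test_boundaries(self, lin112):
        dp = nw_fill("ACGT", "ACG", lin112)
        assert (dp.H[0] == [0, -2, -4, -6]).all()
        assert (dp.H[:, 0] == [0, -2, -4, -6, -8]).all()

    def test_wrong_kernel(self, aff51):
        with pytest.raises(WrongKernelError):
            nw_fill("A", "A", aff51)


class TestNWAlign:
    def test_identity(self, lin112):
        aln = nw_align("ACGT", "ACGT", lin112)
        assert aln.score == 4 and aln.length == 4

    def test_printed_similar_pair(self, lin112):
        # global score of the 9-mer/7-mer example, frozen from the
        # exhaustive plain-Python oracle
        aln = nw_align("ACTTGTCCG", "ATGTCAG", lin112)
        assert aln.score == 1
        assert aln.score == oracles.global_score("ACTTGTCCG", "ATGTCAG", lin112)

    @given(dna, dna)
    def test_score_equals_corner_and_recomputation(self, a, b):
        scheme = ScoringScheme.linear(1, 1, 2)
        dp = nw_fill(a, b, scheme)
        aln = nw_align(a, b, scheme)
        assert aln.score == dp.H[-1, -1]
        assert score_alignment(aln, scheme) == aln.score

    @given(dna, dna)
    def test_matches_exhaustive_oracle(self, a, b):
        scheme = ScoringScheme.linear(1, 1, 2)
        assert nw_fill(a, b, scheme).H[-1, -1] == oracles.global_score(a, b, scheme)


class TestSWFill:
    def test_no_common_residue_scores_zero(self, lin112):
        dp = sw_fill("AAAA", "TTTT", lin112)
        assert dp.H.max() == 0

    def test_printed_local_pair_scores_five(self, lin112, local_pair):
        assert sw_fill(*local_pair, lin112).H.max() == 5

    @given(dna, dna)
    def test_never_negative_and_matches_oracle(self, a, b):
        scheme = ScoringScheme.linear(1, 1, 2)
        H = sw_fill(a, b, scheme).H
        assert H.min() >= 0
        assert H.max() == oracles.local_score(a, b, scheme)


class TestSWBest:
    def test_all_zero_uses_empty_alignment_convention(self, lin112):
        score, cells = sw_best(sw_fill("AAAA", "TTTT", lin112))
        assert score == 0 and cells == []

    def test_printed_pair_has_two_argmax_cells(self, lin112, local_pair):
        score, cells = sw_best(sw_fill(*local_pair, lin112))
        assert score == 5 and len(cells) == 2

    def test_single_match(self, lin112):
        score, cells = sw_best(sw_fill("G", "G", lin112))
        assert (score, cells) == (1, [(1, 1)])


class TestSWAlign:
    def test_printed_pair(self, lin112, local_pair):
        aln = sw_align(*local_pair, lin112)
        assert aln.score == 5
        assert score_alignment(aln, lin112) == 5

    def test_identical_sequences_full_match(self, lin112):
        aln = sw_align("ACGTAC", "ACGTAC", lin112)
        assert aln.score == 6 and aln.length == 6

    def test_empty_target(self, lin112):
        aln = sw_align("ACGT", "", lin112)
        assert aln.score == 0 and aln.columns == []

    @given(dna, dna)
    def test_local_score_at_least_any_single_match(self, a, b):
        scheme = ScoringScheme.linear(1, 1, 2)
        aln = sw_align(a, b, scheme)
        assert score_alignment(aln, scheme) == aln.score
        if set(a) & set(b):
            assert aln.score >= scheme.ma


class TestGotoh:
    def test_single_match_plus_run_of_two(self):
        scheme = ScoringScheme.affine(1, 1, 3, 1)
        assert gotoh_align("AAA", "A", scheme).score == -3  # 1 - gamma(2)

    def test_local_mode_nonnegative(self, aff51, rng):
        a, b = random_dna(rng, 40), random_dna(rng, 35)
        assert gotoh_fill(a, b, aff51, "local").H.min() >= 0

    def test_open_equals_extend_reduces_to_linear(self, lin112, rng):
        scheme = ScoringScheme.affine(1, 1, 2, 2)
        for _ in range(100):
            a = random_dna(rng, int(rng.integers(0, 40)))
            b = random_dna(rng, int(rng.integers(0, 40)))
            assert (
                gotoh_fill(a, b, scheme, "global").H[-1, -1]
                == nw_fill(a, b, lin112).H[-1, -1]
            )
            assert (
                gotoh_fill(a, b, scheme, "local").H.max()
                == sw_fill(a, b, lin112).H.max()
            )

    def test_long_run_charged_gamma_not_per_opening(self):
        scheme = ScoringScheme.affine(1, 0, 5, 1)
        aln = gotoh_align("ACGTACGT", "AT", scheme, "global")
        # gap runs must be charged gamma per run; recomputation enforces it
        assert aln.score == score_alignment(aln, scheme)
        assert aln.score == oracles.global_score("ACGTACGT", "AT", scheme)

    @given(st.text(alphabet="ACGT", max_size=8), st.text(alphabet="ACGT", max_size=8))
    def test_matches_exhaustive_enumeration(self, a, b):
        scheme = ScoringScheme.affine(1, 1, 4, 1)
        got = gotoh_fill(a, b, scheme, "global").H[-1, -1]
        if len(a) + len(b) == 0:
            assert got == 0
            return
        if len(a) <= 5 and len(b) <= 5:
            assert got == oracles.exhaustive_global_best(a, b, scheme)
        assert got == oracles.global_score(a, b, scheme)

    def test_deterministic(self, aff51, rng):
        a, b = random_dna(rng, 50), random_dna(rng, 50)
        aln1 = gotoh_align(a, b, aff51, "global")
        aln2 = gotoh_align(a, b, aff51, "global")
        assert aln1 == aln2

    def test_wrong_kernel(self, lin112):
        with pytest.raises(WrongKernelError):
            gotoh_fill("A", "A", lin112)

    @given(dna1, dna1)
    def test_local_matches_oracle(self, a, b):
        scheme = ScoringScheme.affine(2, 1, 3, 1)
        assert gotoh_fill(a, b, scheme, "local").H.max() == oracles.local_score(
            a, b, scheme
        )


class TestEnumerateOptimalLocal:
    def test_printed_pair_has_exactly_two_optima(self, lin112, local_pair):
        alns = enumerate_optimal_local(*local_pair, lin112)
        assert len(alns) == 2
        assert all(a.score == 5 for a in alns)
        rendered = {
            ("".join(t for t, _ in a.columns), "".join(b for _, b in a.columns))
            for a in alns
        }
        assert rendered == {("AGCTA", "AGCTA"), ("TAT-AGGT", "TATGAGGT")}

    def test_identical_sequences_unique_path(self, lin112):
        alns = enumerate_optimal_local("ACGTT", "ACGTT", lin112)
        assert len(alns) == 1 and alns[0].score == 5

    def test_matches_exhaustive_path_search(self, lin112):
        for a, b in [("AG", "GA"), ("ACG", "GCA"), ("AGCT", "AGT")]:
            got = {tuple(x.columns) for x in enumerate_optimal_local(a, b, lin112)}
            best, want = oracles.exhaustive_local(a, b, lin112)
            assert got == want
            assert all(x.score == best for x in enumerate_optimal_local(a, b, lin112))

    def test_size_guard(self, lin112):
        with pytest.raises(SizeGuardError):
            enumerate_optimal_local("A" * 400, "A" * 400, lin112)

    def test_no_positive_score_yields_nothing(self, lin112):
        assert enumerate_optimal_local("AAAA", "TTTT", lin112) == []


@settings(max_examples=60)
@given(dna, dna)
def test_local_fill_lower_bound_property(a, b):
    """Every local H cell is >= 0 under both gap models."""
    lin = ScoringScheme.linear(1, 1, 2)
    aff = ScoringScheme.affine(1, 1, 3, 1)
    assert sw_fill(a, b, lin).H.min() >= 0
    assert gotoh_fill(a, b, aff, "local").H.min() >= 0
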