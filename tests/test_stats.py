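import io

import pytest

from stagealign import (
    ScoringScheme,
    align_full,
    alignment_stats,
    energy_cost,
    enumerate_optimal_local,
    expected_time_saving,
    gcups,
    petacells,
    speculation_breakeven,
)
from stagealign.core import Alignment
from stagealign.pipeline import PipelineConfig
from stagealign.stats import write_stats_tsv
from conftest import random_dna

# the four published chromosome comparison sizes (human x chimpanzee)
TABLE_SIZES = {
    "chr22": (51_304_566, 49_737_984, 2.55),
    "chr21": (48_129_895, 46_489_110, 2.24),
    "47M": (46_944_323, 32_799_110, 1.54),
    "chrY": (59_373_566, 26_342_871, 1.56),
}


class TestAlignmentStats:
    def test_perfect_match(self, lin112):
        aln = Alignment.build([("A", "A")] * 10, lin112, "global", 1, 1)
        st = alignment_stats(aln, 10, 10)
        assert st.matches_pct == 100.0
        assert st.gaps_pct == 0.0
        assert st.coverage_pct == 100.0
        assert st.length == 10

    def test_match_block_of_the_worked_example(self, lin112, local_pair):
        alns = enumerate_optimal_local(*local_pair, lin112)
        block = next(a for a in alns if a.length == 5)
        st = alignment_stats(block, 12, 12)
        assert st.matches_pct == 100.0 and st.length == 5

    def test_percentages_sum_to_hundred(self, rng):
        scheme = ScoringScheme.affine(1, 1, 5, 1)
        for _ in range(15):
            a = random_dna(rng, int(rng.integers(10, 150)))
            b = random_dna(rng, int(rng.integers(10, 150)))
            out = align_full(a, b, scheme, PipelineConfig(mode="local", workers=2))
            st = out.stats
            if st.length:
                total = st.matches_pct + st.mismatches_pct + st.gaps_pct
                assert total == pytest.approx(100.0, abs=0.1)
                assert 0 <= st.coverage_pct <= 100

    def test_stats_tsv_rows(self, lin112):
        aln = Alignment.build([("A", "A"), ("-", "C")], lin112, "local", 1, 1)
        buf = io.StringIO()
        write_stats_tsv(alignment_stats(aln, 4, 4), buf)
        lines = buf.getvalue().splitlines()
        assert lines[0].startswith("Score\t")
        assert any(ln.startswith("Coverage\t") for ln in lines)


class TestPetacells:
    @pytest.mark.parametrize("name", list(TABLE_SIZES))
    def test_published_sizes(self, name):
        m, n, expected = TABLE_SIZES[name]
        assert round(petacells(m, n), 2) == expected

    def test_simple_power_of_ten(self):
        assert petacells(10**7, 10**8) == 1.0

    def test_domain(self):
        with pytest.raises(ValueError):
            petacells(0, 5)


class TestGcups:
    def test_published_chr22_throughput(self):
        m, n, _ = TABLE_SIZES["chr22"]
        assert round(gcups(m * n, 11361.38), 2) == 224.60

    def test_unit_case(self):
        assert gcups(1e9, 1.0) == 1.0
        assert gcups(0, 10.0) == 0.0

    def test_domain(self):
        with pytest.raises(ValueError):
            gcups(1e9, 0.0)


class TestEnergyCost:
    def test_published_four_gpu_run(self):
        kj, cost = energy_cost(101.33, 11361.38, 4, 0.13)
        assert kj == pytest.approx(1151.27, abs=0.05)
        assert cost == pytest.approx(0.1660, abs=5e-4)

    def test_published_regular_traceback_energy(self):
        kj, _ = energy_cost(160.21, 99.04, 1, 0.0)
        assert kj * 1000 == pytest.approx(15_867.19, abs=1.0)

    def test_zero_runtime(self):
        assert energy_cost(500.0, 0.0, 8, 0.13) == (0.0, 0.0)


class TestSpeculationBreakeven:
    def test_published_deltas_need_ratio_two(self):
        assert speculation_breakeven(-6.5, +11.0) == 2

    @pytest.mark.parametrize("hit,miss,expected", [(-10, 10, 1), (-1, 9, 9)])
    def test_simple_ratios(self, hit, miss, expected):
        assert speculation_breakeven(hit, miss) == expected

    def test_matches_brute_force_search(self):
        for hit in (-0.5, -2.0, -6.5, -13.0):
            for miss in (0.4, 3.0, 11.0, 50.0):
                r = speculation_breakeven(hit, miss)
                brute = next(
                    q for q in range(1, 1001)
                    if (q * hit + miss) / (q + 1) <= 0
                )
                assert r == brute

    def test_sign_violations(self):
        with pytest.raises(ValueError):
            speculation_breakeven(6.5, 11.0)
        with pytest.raises(ValueError):
            speculation_breakeven(-6.5, -11.0)


class TestExpectedTimeSaving:
    def test_published_mixture(self):
        # 18% per hit, ~0% per miss, at the break-even ratio of 2
        assert expected_time_saving(2, 18, 0) == pytest.approx(12.0)

    def test_degenerate_cases(self):
        assert expected_time_saving(0, 55, 0) == 0.0
        for r in (0, 1, 5, 100):
            assert expected_time_saving(r, 7.5, 7.5) == pytest.approx(7.5)

    def test_domain(self):
        with pytest.raises(ValueError):
            expected_time_saving(-1, 1, 1)
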