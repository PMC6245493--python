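"""Alignment characterization and arithmetic cost accounting.

Column percentages (matches / mismatches / gaps) always sum to 100.
Coverage is the mean of the two per-sequence aligned-span fractions: an
alignment spanning rows [start0, end0] of S0 and columns [start1, end1] of
S1 covers (end0-start0+1)/m of one sequence and (end1-start1+1)/n of the
other; coverage_pct averages the two, a documented and swappable policy.

The cost model is pure arithmetic over caller-supplied measurements: this
library never measures power itself.
"""

from __future__ import annotations

import math
from typing import List, TextIO, Tuple

from .core import Alignment, AlignmentStats


def alignment_stats(aln: Alignment, m: int, n: int) -> AlignmentStats:
    """Length, column-class percentages and coverage of an alignment."""
    length = len(aln.columns)
    if length == 0:
        return AlignmentStats(
            length=0, matches_pct=0.0, mismatches_pct=0.0, gaps_pct=0.0,
            coverage_pct=0.0, score=aln.score,
        )
    matches = sum(1 for t, b in aln.columns if t == b and t != "-")
    gaps = sum(1 for t, b in aln.columns if t == "-" or b == "-")
    mismatches = length - matches - gaps
    span0 = max(0, aln.end0 - aln.start0 + 1)
    span1 = max(0, aln.end1 - aln.start1 + 1)
    cov0 = span0 / m if m else 0.0
    cov1 = span1 / n if n else 0.0
    return AlignmentStats(
        length=length,
        matches_pct=100.0 * matches / length,
        mismatches_pct=100.0 * mismatches / length,
        gaps_pct=100.0 * gaps / length,
        coverage_pct=100.0 * (cov0 + cov1) / 2,
        score=aln.score,
    )


def petacells(m: int, n: int) -> float:
    """DP matrix size in units of 10^15 cells (reported at 2 decimals)."""
    if m < 1 or n < 1:
        raise ValueError("petacells requires m, n >= 1")
    return m * n / 1e15


def gcups(cells: float, seconds: float) -> float:
    """Giga cell updates per second: cells / (10^9 * seconds)."""
    if seconds <= 0:
        raise ValueError("gcups requires seconds > 0")
    return cells / (1e9 * seconds)


def energy_cost(
    avg_power_w: float,
    seconds: float,
    n_devices: int,
    tariff_per_kwh: float,
) -> Tuple[float, float]:
    """(kilojoules per device, total cost) from average power and runtime.

    kJ/device = P * t / 1000; cost = n_devices * kWh/device * tariff, with
    kWh = kJ / 3600.
    """
    if avg_power_w < 0 or seconds < 0 or n_devices < 0 or tariff_per_kwh < 0:
        raise ValueError("energy_cost requires non-negative inputs")
    kj = avg_power_w * seconds / 1000.0
    cost = n_devices * (kj / 3600.0) * tariff_per_kwh
    return kj, cost


def speculation_breakeven(delta_e_hit_pct: float, delta_e_miss_pct: float) -> int:
    """Smallest integer hit/miss ratio at which speculation stops costing energy.

    With a per-hit energy delta < 0 and a per-miss delta > 0, r hits per miss
    change energy by (r*hit + miss)/(r+1); the break-even ratio is
    ceil(miss / |hit|).
    """
    if not (delta_e_hit_pct < 0 < delta_e_miss_pct):
        raise ValueError("requires delta_e_hit_pct < 0 < delta_e_miss_pct")
    return math.ceil(delta_e_miss_pct / abs(delta_e_hit_pct))


def expected_time_saving(
    ratio: float, per_hit_saving_pct: float, per_miss_saving_pct: float
) -> float:
    """Mean time saving at a given hit/miss ratio: (r*hit + miss)/(r+1)."""
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    return (ratio * per_hit_saving_pct + per_miss_saving_pct) / (ratio + 1)


def write_stats_tsv(stats: AlignmentStats, fh: TextIO) -> None:
    """One metric per row, mirroring the comparison-table row labels."""
    rows: List[Tuple[str, str]] = [
        ("Score", str(stats.score)),
        ("Length", str(stats.length)),
        ("Coverage", f"{stats.coverage_pct:.1f}%"),
        ("Matches", f"{stats.matches_pct:.1f}%"),
        ("Mismatches", f"{stats.mismatches_pct:.1f}%"),
        ("Gaps", f"{stats.gaps_pct:.1f}%"),
    ]
    for key, val in rows:
        fh.write(f"{key}\t{val}\n")
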