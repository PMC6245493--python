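"""Anti-diagonal scheduling and linear-memory band evaluation.

The DP recurrences let every cell of an anti-diagonal be computed
independently once the previous two diagonals are known; the schedule below
exposes that order.  The band engine evaluates a contiguous column range
("band") of the matrix given the true border column to its left, sweeping
rows with two working rows of state -- an order with the same dependency
structure, chosen because its outputs are bit-identical and it vectorizes
well on a CPU.  A band emits exactly what the staged pipeline needs: its
right border column (H, plus E so horizontal gap runs cross borders
exactly), checkpointed special rows (H, plus F for vertical runs), and the
band's best cell in local mode.
"""

from __future__ import annotations

import math
from typing import List, Optional, Tuple

import numpy as np

from . import _kernels, reference
from .core import (
    NEG,
    BorderColumn,
    DataflowError,
    Partition,
    ScoringScheme,
    SpecialRows,
    gamma,
    pair_encoding,
)
from .reference import SequenceLike, _residues


def antidiagonal_schedule(m: int, n: int) -> List[List[Tuple[int, int]]]:
    """The m+n-1 anti-diagonals of the interior grid, each a list of (i, j).

    Diagonal d (1-based) holds the cells with i+j-1 == d; per-diagonal cell
    counts rise 1..min(m, n), plateau, and fall back to 1.
    """
    if m < 1 or n < 1:
        raise ValueError("schedule requires m, n >= 1")
    diags = []
    for d in range(1, m + n):
        lo = max(1, d + 1 - n)
        hi = min(m, d)
        diags.append([(i, d + 1 - i) for i in range(lo, hi + 1)])
    return diags


def max_parallelism(m: int, n: int) -> int:
    """Cells computable in parallel on the widest diagonal: min(m, n)."""
    if m < 1 or n < 1:
        raise ValueError("max_parallelism requires m, n >= 1")
    return min(m, n)


def default_special_interval(m: int) -> int:
    return max(1, math.ceil(m / 100))


def boundary_border(m: int, scheme: ScoringScheme, mode: str) -> BorderColumn:
    """The synthetic border column 0 (the global DP boundary)."""
    if mode == "local":
        h = np.zeros(m + 1, np.int64)
    elif scheme.is_affine:
        i = np.arange(m + 1, dtype=np.int64)
        h = np.where(i > 0, -(scheme.G_open + (i - 1) * scheme.G_ext), 0).astype(np.int64)
    else:
        h = (-scheme.G * np.arange(m + 1, dtype=np.int64)).astype(np.int64)
    e = np.full(m + 1, NEG, np.int64) if scheme.is_affine else None
    return BorderColumn(partition_index=-1, j=0, h=h, e=e)


def _top_row(scheme: ScoringScheme, mode: str, j_from: int, j_to: int) -> np.ndarray:
    """Monolithic row-0 H values over columns j_from..j_to inclusive."""
    js = np.arange(j_from, j_to + 1, dtype=np.int64)
    if mode == "local":
        return np.zeros(js.shape[0], np.int64)
    if scheme.is_affine:
        return np.where(js > 0, -(scheme.G_open + (js - 1) * scheme.G_ext), 0).astype(np.int64)
    return (-scheme.G * js).astype(np.int64)


def band_fill(
    S0: SequenceLike,
    S1: SequenceLike,
    partition: Partition,
    scheme: ScoringScheme,
    mode: str = "local",
    in_border: Optional[BorderColumn] = None,
    k: Optional[int] = None,
) -> Tuple[BorderColumn, SpecialRows, Optional[Tuple[int, Tuple[int, int]]]]:
    """Fill one column band given the true border column to its left.

    Returns the band's right border column (equal, cell for cell, to the
    monolithic DP column j_hi), the special rows {k, 2k, ..., m} restricted
    to the band's columns, and in local mode the band's best (score, cell).
    """
    r0, r1 = _residues(S0), _residues(S1)
    m = len(r0)
    if m < 1:
        raise DataflowError("band_fill requires a non-empty S0")
    if partition.j_hi > len(r1):
        raise DataflowError("partition exceeds S1")
    if k is None:
        k = default_special_interval(m)
    if in_border is None:
        if partition.j_lo != 1:
            raise DataflowError("only the first band may omit its in-border")
        in_border = boundary_border(m, scheme, mode)
    if in_border.h.shape[0] != m + 1:
        raise DataflowError(
            f"in-border has {in_border.h.shape[0]} rows, expected {m + 1}"
        )
    if scheme.is_affine and in_border.e is None:
        raise DataflowError("affine band_fill requires E values on the in-border")

    band = r1[partition.j_lo - 1 : partition.j_hi]
    w = len(band)
    c0, c1b, pmat = pair_encoding(r0, band, scheme)
    spec_idx = np.array(sorted(set(range(k, m + 1, k)) | {m}), np.int64)
    top_h = _top_row(scheme, mode, partition.j_lo - 1, partition.j_hi)
    local = mode == "local"

    if scheme.is_affine:
        top_f = np.full(w + 1, NEG, np.int64)
        out_h, out_e, spec_h, spec_f, best, bi, bj = _kernels.band_affine(
            c0, c1b, pmat, scheme.G_open, scheme.G_ext, local,
            top_h, top_f, in_border.h, in_border.e, spec_idx,
        )
        out_e[0] = NEG if local else -gamma(partition.j_hi, scheme)
        border = BorderColumn(partition.index, partition.j_hi, h=out_h, e=out_e)
        rows = {int(r): (spec_h[t].copy(), spec_f[t].copy()) for t, r in enumerate(spec_idx)}
    else:
        out_h, spec_h, best, bi, bj = _kernels.band_linear(
            c0, c1b, pmat, scheme.G, local, top_h, in_border.h, spec_idx
        )
        border = BorderColumn(partition.index, partition.j_hi, h=out_h)
        rows = {int(r): (spec_h[t].copy(), None) for t, r in enumerate(spec_idx)}

    specials = SpecialRows(interval=k, j_lo=partition.j_lo, j_hi=partition.j_hi, rows=rows)
    local_best = None
    if local:
        if best > 0:
            local_best = (int(best), (int(bi), int(bj) + partition.j_lo - 1))
        else:
            local_best = (0, None)
    return border, specials, local_best
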