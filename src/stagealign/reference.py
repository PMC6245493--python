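"""Quadratic-space reference kernels with full traceback.

Needleman-Wunsch (global, linear gaps), Smith-Waterman (local, linear gaps)
and Gotoh (affine gaps, global or local), plus exhaustive enumeration of all
co-optimal local alignments at toy scale.  These are the ground truth the
linear-space and pipelined engines are tested against.

Traceback tie-breaks are fixed and documented: in H, diagonal before the
vertical branch before the horizontal branch for linear gaps, and diagonal
before the E (horizontal) branch before the F (vertical) branch for affine
gaps; inside a gap matrix, closing the run (OPEN) before extending it.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from . import _kernels
from .core import (
    DIAG,
    EXT,
    LEFT,
    NEG,
    OPEN,
    STOP,
    UP,
    Alignment,
    DPMatrices,
    ScoringScheme,
    Sequence,
    SizeGuardError,
    WrongKernelError,
    gamma,
    pair_encoding,
)

SequenceLike = Union[Sequence, str]


def _residues(s: SequenceLike) -> str:
    return s.residues if isinstance(s, Sequence) else Sequence("anon", s).residues


def _require(scheme: ScoringScheme, gap_model: str) -> None:
    if scheme.gap_model != gap_model:
        raise WrongKernelError(
            f"kernel requires the {gap_model} gap model, got {scheme.gap_model}"
        )


# thin wrappers around the jitted fills; everything quadratic allocates
# through these two functions, which keeps the linear-space memory contract
# observable (tests can intercept them and record matrix areas).


def _run_fill_linear(c0, c1, pmat, G, local, top_h, left_h):
    return _kernels.fill_linear(c0, c1, pmat, G, local, top_h, left_h)


def _run_fill_affine(c0, c1, pmat, Go, Ge, local, top_h, top_e, top_f, left_h, left_e, left_f):
    return _kernels.fill_affine(
        c0, c1, pmat, Go, Ge, local, top_h, top_e, top_f, left_h, left_e, left_f
    )


def linear_boundaries(m: int, n: int, scheme: ScoringScheme, mode: str):
    if mode == "local":
        return np.zeros(n + 1, np.int64), np.zeros(m + 1, np.int64)
    G = scheme.G
    return -G * np.arange(n + 1, dtype=np.int64), -G * np.arange(m + 1, dtype=np.int64)


def affine_boundaries(
    m: int,
    n: int,
    scheme: ScoringScheme,
    mode: str,
    start_gap: Optional[str] = None,
    force_start: Optional[str] = None,
) -> Dict[str, np.ndarray]:
    """Boundary arrays for the three-matrix fill.

    ``start_gap`` ('E' or 'F') waives the opening penalty of a leading gap
    run on that axis: the run continues one that was opened before this
    subproblem.  ``force_start`` constrains the path to begin with a gap run
    on that axis at full charge (used to evaluate reverse vectors whose far
    end is pinned inside a run).  At most one of the two may be set.
    """
    Go, Ge = scheme.G_open, scheme.G_ext
    js = np.arange(n + 1, dtype=np.int64)
    is_ = np.arange(m + 1, dtype=np.int64)
    gj = np.where(js > 0, -(Go + (js - 1) * Ge), 0).astype(np.int64)
    gi = np.where(is_ > 0, -(Go + (is_ - 1) * Ge), 0).astype(np.int64)
    neg_j = np.full(n + 1, NEG, np.int64)
    neg_i = np.full(m + 1, NEG, np.int64)
    if mode == "local":
        b = dict(
            top_h=np.zeros(n + 1, np.int64),
            top_e=neg_j.copy(),
            top_f=neg_j.copy(),
            left_h=np.zeros(m + 1, np.int64),
            left_e=neg_i.copy(),
            left_f=neg_i.copy(),
        )
        return b
    top_h, top_e, top_f = gj.copy(), gj.copy(), neg_j.copy()
    left_h, left_e, left_f = gi.copy(), neg_i.copy(), gi.copy()
    top_e[0] = NEG
    left_f[0] = NEG
    if start_gap == "F":
        left_h = (-Ge * is_).astype(np.int64)
        left_f = (-Ge * is_).astype(np.int64)  # corner 0 lets EXT arrows end at the origin
    elif start_gap == "E":
        top_h = (-Ge * js).astype(np.int64)
        top_e = (-Ge * js).astype(np.int64)
        left_e = neg_i.copy()
        left_e[0] = 0  # the kernel takes the corner from the left arrays
    if force_start == "F":
        top_h = neg_j.copy()
        top_e = neg_j.copy()
        left_h = gi.copy()
        left_f = gi.copy()
        left_f[0] = NEG
        left_h[0] = NEG  # the path may not pass through the origin in H
    elif force_start == "E":
        left_h = neg_i.copy()
        left_e = neg_i.copy()
        left_f = neg_i.copy()
        top_h = gj.copy()
        top_e = gj.copy()
        top_e[0] = NEG
        top_h[0] = NEG
    return dict(
        top_h=top_h, top_e=top_e, top_f=top_f, left_h=left_h, left_e=left_e, left_f=left_f
    )


def _pmatrix(c0: np.ndarray, c1: np.ndarray, pmat: np.ndarray) -> np.ndarray:
    return pmat[c0[:, None], c1[None, :]]


def arrows_linear(H: np.ndarray, P: np.ndarray, G: int, local: bool) -> np.ndarray:
    a = np.zeros(H.shape, np.uint8)
    a[1:, 1:] |= ((H[1:, 1:] == H[:-1, :-1] + P) * DIAG).astype(np.uint8)
    a[1:, :] |= ((H[1:, :] == H[:-1, :] - G) * UP).astype(np.uint8)
    a[:, 1:] |= ((H[:, 1:] == H[:, :-1] - G) * LEFT).astype(np.uint8)
    if local:
        a |= ((H == 0) * STOP).astype(np.uint8)
    return a


def arrows_affine(
    H: np.ndarray, E: np.ndarray, F: np.ndarray, P: np.ndarray, Go: int, Ge: int, local: bool
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    aH = np.zeros(H.shape, np.uint8)
    aH[1:, 1:] |= ((H[1:, 1:] == H[:-1, :-1] + P) * DIAG).astype(np.uint8)
    aH |= ((H == E) * LEFT).astype(np.uint8)
    aH |= ((H == F) * UP).astype(np.uint8)
    if local:
        aH |= ((H == 0) * STOP).astype(np.uint8)
    aE = np.zeros(H.shape, np.uint8)
    aE[:, 1:] |= ((E[:, 1:] == E[:, :-1] - Ge) * EXT).astype(np.uint8)
    aE[:, 1:] |= ((E[:, 1:] == H[:, :-1] - Go) * OPEN).astype(np.uint8)
    aF = np.zeros(H.shape, np.uint8)
    aF[1:, :] |= ((F[1:, :] == F[:-1, :] - Ge) * EXT).astype(np.uint8)
    aF[1:, :] |= ((F[1:, :] == H[:-1, :] - Go) * OPEN).astype(np.uint8)
    return aH, aE, aF


def _fill_linear_dp(r0: str, r1: str, scheme: ScoringScheme, mode: str) -> DPMatrices:
    c0, c1, pmat = pair_encoding(r0, r1, scheme)
    top_h, left_h = linear_boundaries(len(r0), len(r1), scheme, mode)
    H = _run_fill_linear(c0, c1, pmat, scheme.G, mode == "local", top_h, left_h)
    arrows = arrows_linear(H, _pmatrix(c0, c1, pmat), scheme.G, mode == "local")
    return DPMatrices(H=H, mode=mode, arrows=arrows)


def _fill_affine_dp(
    r0: str,
    r1: str,
    scheme: ScoringScheme,
    mode: str,
    start_gap: Optional[str] = None,
    force_start: Optional[str] = None,
) -> DPMatrices:
    c0, c1, pmat = pair_encoding(r0, r1, scheme)
    b = affine_boundaries(len(r0), len(r1), scheme, mode, start_gap, force_start)
    H, E, F = _run_fill_affine(
        c0, c1, pmat, scheme.G_open, scheme.G_ext, mode == "local",
        b["top_h"], b["top_e"], b["top_f"], b["left_h"], b["left_e"], b["left_f"],
    )
    aH, aE, aF = arrows_affine(
        H, E, F, _pmatrix(c0, c1, pmat), scheme.G_open, scheme.G_ext, mode == "local"
    )
    return DPMatrices(H=H, E=E, F=F, mode=mode, arrows=aH, arrows_e=aE, arrows_f=aF)


def nw_fill(S0: SequenceLike, S1: SequenceLike, scheme: ScoringScheme) -> DPMatrices:
    """Global linear-gap DP matrix; boundaries -G*i / -G*j, optimum at H[m][n]."""
    _require(scheme, "linear")
    return _fill_linear_dp(_residues(S0), _residues(S1), scheme, "global")


def sw_fill(S0: SequenceLike, S1: SequenceLike, scheme: ScoringScheme) -> DPMatrices:
    """Local linear-gap DP matrix; zero boundaries, no negative cells."""
    _require(scheme, "linear")
    return _fill_linear_dp(_residues(S0), _residues(S1), scheme, "local")


def gotoh_fill(
    S0: SequenceLike, S1: SequenceLike, scheme: ScoringScheme, mode: str = "global"
) -> DPMatrices:
    """Affine-gap three-matrix DP (H, E, F); the zero branch only in local mode."""
    _require(scheme, "affine")
    if mode not in ("global", "local"):
        raise ValueError(f"unknown mode {mode!r}")
    return _fill_affine_dp(_residues(S0), _residues(S1), scheme, mode)


def sw_best(dp: DPMatrices) -> Tuple[int, List[Tuple[int, int]]]:
    """Maximum local score and every cell attaining it, row-major.

    An all-zero matrix reports score 0 with no cells: the empty-alignment
    convention.
    """
    best = int(dp.H.max()) if dp.H.size else 0
    if best <= 0:
        return 0, []
    cells = [(int(i), int(j)) for i, j in np.argwhere(dp.H == best)]
    return best, cells


def _best_cell(cells: List[Tuple[int, int]]) -> Tuple[int, int]:
    return min(cells, key=lambda c: (c[0] + c[1], c[0]))


def _tb_linear(
    r0: str, r1: str, H: np.ndarray, arrows: np.ndarray, i: int, j: int, local: bool
):
    cols: List[Tuple[str, str]] = []
    while True:
        if local and H[i, j] == 0:
            break
        if i == 0 and j == 0:
            break
        b = arrows[i, j]
        if b & DIAG:
            cols.append((r0[i - 1], r1[j - 1]))
            i -= 1
            j -= 1
        elif b & UP:
            cols.append((r0[i - 1], "-"))
            i -= 1
        elif b & LEFT:
            cols.append(("-", r1[j - 1]))
            j -= 1
        else:  # pragma: no cover - would indicate a fill/arrow inconsistency
            raise RuntimeError(f"no arrow at ({i}, {j})")
    cols.reverse()
    return cols, i, j


def _tb_affine(
    r0: str,
    r1: str,
    dp: DPMatrices,
    i: int,
    j: int,
    state: str,
    local: bool,
):
    cols: List[Tuple[str, str]] = []
    H, aH, aE, aF = dp.H, dp.arrows, dp.arrows_e, dp.arrows_f
    while True:
        if i == 0 and j == 0:
            break
        if state == "H":
            if local and H[i, j] == 0:
                break
            b = aH[i, j]
            if b & DIAG:
                cols.append((r0[i - 1], r1[j - 1]))
                i -= 1
                j -= 1
            elif b & LEFT:
                state = "E"
            elif b & UP:
                state = "F"
            else:  # pragma: no cover
                raise RuntimeError(f"no arrow at H({i}, {j})")
        elif state == "E":
            cols.append(("-", r1[j - 1]))
            b = aE[i, j]
            j -= 1
            state = "H" if b & OPEN else "E"
            if not b:  # pragma: no cover
                raise RuntimeError("no arrow in E")
        else:
            cols.append((r0[i - 1], "-"))
            b = aF[i, j]
            i -= 1
            state = "H" if b & OPEN else "F"
            if not b:  # pragma: no cover
                raise RuntimeError("no arrow in F")
    cols.reverse()
    return cols, i, j


def nw_align(S0: SequenceLike, S1: SequenceLike, scheme: ScoringScheme) -> Alignment:
    """One optimal global alignment; ties broken diagonal > up > left."""
    r0, r1 = _residues(S0), _residues(S1)
    dp = nw_fill(r0, r1, scheme)
    cols, _, _ = _tb_linear(r0, r1, dp.H, dp.arrows, len(r0), len(r1), local=False)
    return Alignment.build(cols, scheme, "global", 1, 1)


def sw_align(S0: SequenceLike, S1: SequenceLike, scheme: ScoringScheme) -> Alignment:
    """One optimal local alignment from the tie-broken best cell.

    Best-cell ties resolve to the smallest i+j, then the smallest i; the
    traceback stops before the first zero-valued cell.
    """
    r0, r1 = _residues(S0), _residues(S1)
    dp = sw_fill(r0, r1, scheme)
    best, cells = sw_best(dp)
    if best == 0:
        return Alignment.build([], scheme, "local", 1, 1)
    i, j = _best_cell(cells)
    cols, i0, j0 = _tb_linear(r0, r1, dp.H, dp.arrows, i, j, local=True)
    return Alignment.build(cols, scheme, "local", i0 + 1, j0 + 1)


def gotoh_align(
    S0: SequenceLike, S1: SequenceLike, scheme: ScoringScheme, mode: str = "global"
) -> Alignment:
    """One optimal affine-gap alignment; H ties resolve diag > E > F."""
    r0, r1 = _residues(S0), _residues(S1)
    dp = gotoh_fill(r0, r1, scheme, mode)
    if mode == "local":
        best, cells = sw_best(dp)
        if best == 0:
            return Alignment.build([], scheme, "local", 1, 1)
        i, j = _best_cell(cells)
    else:
        i, j = len(r0), len(r1)
    cols, i0, j0 = _tb_affine(r0, r1, dp, i, j, "H", mode == "local")
    if mode == "global":
        return Alignment.build(cols, scheme, "global", 1, 1)
    return Alignment.build(cols, scheme, "local", i0 + 1, j0 + 1)


def enumerate_optimal_local(
    S0: SequenceLike, S1: SequenceLike, scheme: ScoringScheme
) -> List[Alignment]:
    """All distinct optimal local alignments (toy scale, m*n <= 1e5 guarded).

    Starts a traceback at every argmax cell and branches on every maximizing
    arrow, stopping at zero cells; identical column lists are deduplicated.
    Returns [] when the best score is 0 (the empty-alignment convention).
    """
    r0, r1 = _residues(S0), _residues(S1)
    if len(r0) * len(r1) > 100_000:
        raise SizeGuardError("enumeration guarded at m*n <= 1e5")
    if scheme.is_affine:
        dp = gotoh_fill(r0, r1, scheme, "local")
    else:
        dp = sw_fill(r0, r1, scheme)
    best, cells = sw_best(dp)
    if best == 0:
        return []
    seen: Dict[tuple, Alignment] = {}
    H, aH = dp.H, dp.arrows
    aE, aF = dp.arrows_e, dp.arrows_f
    acc: List[Tuple[str, str]] = []

    def emit(i: int, j: int) -> None:
        key = tuple(reversed(acc))
        if key not in seen:
            seen[key] = Alignment.build(list(key), scheme, "local", i + 1, j + 1)

    def walk(state: str, i: int, j: int) -> None:
        if state == "H":
            if H[i, j] == 0:
                emit(i, j)
                return
            b = aH[i, j]
            if b & DIAG:
                acc.append((r0[i - 1], r1[j - 1]))
                walk("H", i - 1, j - 1)
                acc.pop()
            if scheme.is_affine:
                if b & LEFT:
                    walk("E", i, j)
                if b & UP:
                    walk("F", i, j)
            else:
                if b & UP:
                    acc.append((r0[i - 1], "-"))
                    walk("H", i - 1, j)
                    acc.pop()
                if b & LEFT:
                    acc.append(("-", r1[j - 1]))
                    walk("H", i, j - 1)
                    acc.pop()
        elif state == "E":
            b = aE[i, j]
            acc.append(("-", r1[j - 1]))
            if b & OPEN:
                walk("H", i, j - 1)
            if b & EXT:
                walk("E", i, j - 1)
            acc.pop()
        else:
            b = aF[i, j]
            acc.append((r0[i - 1], "-"))
            if b & OPEN:
                walk("H", i - 1, j)
            if b & EXT:
                walk("F", i - 1, j)
            acc.pop()

    for i, j in cells:
        walk("H", i, j)
    return list(seen.values())
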