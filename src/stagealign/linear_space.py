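"""Linear-memory optimal alignment by divide and conquer.

The global DP is evaluated forward to the middle row and backward (over the
reversed sequences) from the end to the middle row, keeping only the last
row of scores.  The column where forward plus reverse scores is maximal is
the midpoint, a cell on an optimal path; the problem splits there and
recurses until subproblems are small enough for direct quadratic DP.

With affine gaps (the Myers-Miller extension) a second vector pair,
constrained to end (forward) or begin (reverse) with a vertical gap, detects
midpoints that fall inside a gap run.  Joining the two halves of a run of
length x = x1 + x2 must charge gamma(x) once, while the constrained vectors
charge gamma(x1) + gamma(x2) = gamma(x) + (G_open - G_ext); the junction
correction is therefore +(G_open - G_ext).  The split then forces the left
child to end in the vertical-gap state and waives the opening penalty of the
right child's leading vertical run, so concatenated children always charge
exactly gamma(x).
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from . import _kernels, reference
from .core import (
    NEG,
    Alignment,
    MidpointVectors,
    ScoringScheme,
    Sequence,
    WrongKernelError,
    pair_encoding,
)
from .reference import SequenceLike, _residues

DEFAULT_BASE_CASE_AREA = 4096


def _vectors_affine(
    r0seg: str,
    r1: str,
    scheme: ScoringScheme,
    start_gap: Optional[str] = None,
    force_start: Optional[str] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Last-row score vectors (CC, DD) of the forward affine DP.

    CC(j): best score aligning the whole segment to S1[1..j].  DD(j): best
    such score for paths ending with a vertical gap (in the F state), the
    quantity a run needs to cross the middle row.  O(n) working memory.
    """
    m, n = len(r0seg), len(r1)
    b = reference.affine_boundaries(m, n, scheme, "global", start_gap, force_start)
    if m == 0:
        return b["top_h"].copy(), np.full(n + 1, NEG, np.int64)
    c0, c1, pmat = pair_encoding(r0seg, r1, scheme)
    out = _kernels.band_affine(
        c0, c1, pmat, scheme.G_open, scheme.G_ext, False,
        b["top_h"], b["top_f"], b["left_h"], b["left_e"],
        np.array([m], np.int64),
    )
    _, _, spec_h, spec_f, _, _, _ = out
    CC = np.concatenate(([b["left_h"][m]], spec_h[0]))
    DD = np.concatenate(([b["left_f"][m]], spec_f[0]))
    return CC, DD


def _vectors_linear(r0seg: str, r1: str, scheme: ScoringScheme) -> np.ndarray:
    m, n = len(r0seg), len(r1)
    top_h, left_h = reference.linear_boundaries(m, n, scheme, "global")
    if m == 0:
        return top_h.copy()
    c0, c1, pmat = pair_encoding(r0seg, r1, scheme)
    _, spec_h, _, _, _ = _kernels.band_linear(
        c0, c1, pmat, scheme.G, False, top_h, left_h, np.array([m], np.int64)
    )
    return np.concatenate(([left_h[m]], spec_h[0]))


def forward_vectors(
    S0_prefix: SequenceLike, S1: SequenceLike, scheme: ScoringScheme
) -> Tuple[np.ndarray, np.ndarray]:
    """(CC, DD) for the prefix S0[1..i*] against all prefixes of S1."""
    if not scheme.is_affine:
        raise WrongKernelError("forward_vectors requires the affine gap model")
    return _vectors_affine(_residues(S0_prefix), _residues(S1), scheme)


def reverse_vectors(
    S0_suffix: SequenceLike, S1: SequenceLike, scheme: ScoringScheme
) -> Tuple[np.ndarray, np.ndarray]:
    """(RR, SS): forward vectors of the reversed suffix against reversed S1.

    RR(x) is the best score aligning the suffix to the last x residues of
    S1; SS(x) additionally requires the alignment to begin (in the original
    orientation) with a vertical gap.
    """
    if not scheme.is_affine:
        raise WrongKernelError("reverse_vectors requires the affine gap model")
    return _vectors_affine(_residues(S0_suffix)[::-1], _residues(S1)[::-1], scheme)


def _match_midpoint(
    r0: str,
    r1: str,
    scheme: ScoringScheme,
    start_gap: Optional[str],
    end_gap: Optional[str],
) -> Tuple[int, int, bool, int, MidpointVectors]:
    """Midpoint (i*, j*) plus whether it falls inside a vertical gap run.

    Returns (i_star, j_star, in_gap, achieved, vectors); ``achieved`` equals
    the subproblem's optimal score.
    """
    m, n = len(r0), len(r1)
    i_star = m // 2
    if scheme.is_affine:
        CC, DD = _vectors_affine(r0[:i_star], r1, scheme, start_gap=start_gap)
        RR, SS = _vectors_affine(
            r0[i_star:][::-1], r1[::-1], scheme, force_start=end_gap
        )
        corr = scheme.G_open - scheme.G_ext
        t1 = CC + RR[::-1]
        t2 = DD + SS[::-1] + corr
        best = int(max(t1.max(), t2.max()))
        j1 = int(np.argmax(t1 == best)) if (t1 == best).any() else n + 1
        j2 = int(np.argmax(t2 == best)) if (t2 == best).any() else n + 1
        if j1 <= j2:
            j_star, in_gap = j1, False
        else:
            j_star, in_gap = j2, True
        vec = MidpointVectors(CC=CC, DD=DD, RR=RR, SS=SS, i_star=i_star, j_star=j_star)
        return i_star, j_star, in_gap, best, vec
    CC = _vectors_linear(r0[:i_star], r1, scheme)
    RR = _vectors_linear(r0[i_star:][::-1], r1[::-1], scheme)
    t1 = CC + RR[::-1]
    best = int(t1.max())
    j_star = int(np.argmax(t1 == best))
    vec = MidpointVectors(CC=CC, DD=CC, RR=RR, SS=RR, i_star=i_star, j_star=j_star)
    return i_star, j_star, False, best, vec


def mm_midpoint(
    S0: SequenceLike, S1: SequenceLike, scheme: ScoringScheme
) -> Tuple[int, int]:
    """The divide-and-conquer midpoint (i*, j*); i* = floor(m/2), ties to the
    smallest j*.  Requires m >= 2 (smaller problems go straight to DP)."""
    r0, r1 = _residues(S0), _residues(S1)
    if len(r0) < 2:
        raise ValueError("midpoint requires m >= 2; solve the base case directly")
    i_star, j_star, _, _, _ = _match_midpoint(r0, r1, scheme, None, None)
    return i_star, j_star


def midpoint_vectors(
    S0: SequenceLike, S1: SequenceLike, scheme: ScoringScheme
) -> MidpointVectors:
    r0, r1 = _residues(S0), _residues(S1)
    if len(r0) < 2:
        raise ValueError("midpoint requires m >= 2; solve the base case directly")
    return _match_midpoint(r0, r1, scheme, None, None)[4]


def _direct_align(
    r0: str,
    r1: str,
    scheme: ScoringScheme,
    start_gap: Optional[str],
    end_gap: Optional[str],
) -> List[Tuple[str, str]]:
    """Quadratic-space base case with gap-state boundary conditions."""
    m, n = len(r0), len(r1)
    if scheme.is_affine:
        dp = reference._fill_affine_dp(r0, r1, scheme, "global", start_gap=start_gap)
        state = end_gap if end_gap in ("E", "F") else "H"
        cols, _, _ = reference._tb_affine(r0, r1, dp, m, n, state, local=False)
        return cols
    dp = reference._fill_linear_dp(r0, r1, scheme, "global")
    cols, _, _ = reference._tb_linear(r0, r1, dp.H, dp.arrows, m, n, local=False)
    return cols


def mm_align_segment(
    r0: str,
    r1: str,
    scheme: ScoringScheme,
    start_gap: Optional[str] = None,
    end_gap: Optional[str] = None,
    base_case_area: int = DEFAULT_BASE_CASE_AREA,
) -> List[Tuple[str, str]]:
    """Columns of one optimal global alignment of a bounded segment.

    ``start_gap`` waives the opening penalty of a leading run on that axis
    (the run was opened before this segment); ``end_gap`` forces the path to
    end mid-run on that axis.  Linear-memory except for base cases of area
    <= ``base_case_area``.
    """
    m, n = len(r0), len(r1)
    if m == 0:
        return [("-", b) for b in r1]
    if n == 0:
        return [(a, "-") for a in r0]
    if m < 2 or m * n <= base_case_area:
        return _direct_align(r0, r1, scheme, start_gap, end_gap)
    i_star, j_star, in_gap, _, _ = _match_midpoint(r0, r1, scheme, start_gap, end_gap)
    mid = "F" if in_gap else None
    left = mm_align_segment(
        r0[:i_star], r1[:j_star], scheme, start_gap, mid, base_case_area
    )
    right = mm_align_segment(
        r0[i_star:], r1[j_star:], scheme, mid, end_gap, base_case_area
    )
    return left + right


def _locate_local_best(r0: str, r1: str, scheme: ScoringScheme):
    """Best local cell (score, i, j) using an O(n)-memory sweep."""
    m, n = len(r0), len(r1)
    c0, c1, pmat = pair_encoding(r0, r1, scheme)
    spec = np.array([m], np.int64)
    if scheme.is_affine:
        b = reference.affine_boundaries(m, n, scheme, "local")
        out = _kernels.band_affine(
            c0, c1, pmat, scheme.G_open, scheme.G_ext, True,
            b["top_h"], b["top_f"], b["left_h"], b["left_e"], spec,
        )
        best, bi, bj = out[4], out[5], out[6]
    else:
        top_h, left_h = reference.linear_boundaries(m, n, scheme, "local")
        out = _kernels.band_linear(c0, c1, pmat, scheme.G, True, top_h, left_h, spec)
        best, bi, bj = out[2], out[3], out[4]
    return int(best), int(bi), int(bj)


def linear_align(
    S0: SequenceLike,
    S1: SequenceLike,
    scheme: ScoringScheme,
    mode: str = "global",
    base_case_area: int = DEFAULT_BASE_CASE_AREA,
) -> Alignment:
    """One optimal alignment in linear memory.

    Global mode runs the divide-and-conquer directly.  Local mode first
    locates the optimal end cell with a forward local sweep and the start
    cell with a reverse sweep over the bounded prefix, then aligns the
    bounded subproblem globally.
    """
    r0, r1 = _residues(S0), _residues(S1)
    if mode == "global":
        cols = mm_align_segment(r0, r1, scheme, None, None, base_case_area)
        return Alignment.build(cols, scheme, "global", 1, 1)
    if mode != "local":
        raise ValueError(f"unknown mode {mode!r}")
    best, ie, je = _locate_local_best(r0, r1, scheme)
    if best <= 0:
        return Alignment.build([], scheme, "local", 1, 1)
    rbest, bi, bj = _locate_local_best(r0[:ie][::-1], r1[:je][::-1], scheme)
    i0, j0 = ie - bi, je - bj
    cols = mm_align_segment(r0[i0:ie], r1[j0:je], scheme, None, None, base_case_area)
    return Alignment.build(cols, scheme, "local", i0 + 1, j0 + 1)
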