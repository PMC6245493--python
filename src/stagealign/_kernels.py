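"""Jitted DP inner loops.

Two families of kernels:

* full fills returning the whole (m+1) x (n+1) matrix/matrices, driven by
  explicit boundary arrays so the same kernel serves the global, local,
  gap-waived and gap-forced initializations as well as band strips whose
  boundaries come from checkpoints;
* band fills that sweep rows keeping only two working rows, emitting the
  right border column, the checkpointed special rows and the band's best
  cell -- the linear-memory engine behind the wavefront/pipeline modules.

All arithmetic is int64; boundary "minus infinity" cells use a sentinel far
from the int64 limit so gap subtractions cannot wrap.
"""

import numpy as np
from numba import njit

NEG = np.int64(-(1 << 60))


@njit(cache=True)
def fill_linear(c0, c1, pmat, G, local, top_h, left_h):
    """Full linear-gap DP matrix with given boundary row/column."""
    m = c0.shape[0]
    n = c1.shape[0]
    H = np.empty((m + 1, n + 1), np.int64)
    for j in range(n + 1):
        H[0, j] = top_h[j]
    for i in range(m + 1):
        H[i, 0] = left_h[i]
    for i in range(1, m + 1):
        a = c0[i - 1]
        for j in range(1, n + 1):
            v = H[i - 1, j - 1] + pmat[a, c1[j - 1]]
            u = H[i - 1, j] - G
            if u > v:
                v = u
            w = H[i, j - 1] - G
            if w > v:
                v = w
            if local and v < 0:
                v = 0
            H[i, j] = v
    return H


@njit(cache=True)
def fill_affine(c0, c1, pmat, Go, Ge, local, top_h, top_e, top_f, left_h, left_e, left_f):
    """Full affine-gap (three-matrix) DP with given boundaries.

    E tracks runs of gaps in S0 (left moves, consuming S1); F tracks runs of
    gaps in S1 (up moves, consuming S0).
    """
    m = c0.shape[0]
    n = c1.shape[0]
    H = np.empty((m + 1, n + 1), np.int64)
    E = np.empty((m + 1, n + 1), np.int64)
    F = np.empty((m + 1, n + 1), np.int64)
    for j in range(n + 1):
        H[0, j] = top_h[j]
        E[0, j] = top_e[j]
        F[0, j] = top_f[j]
    for i in range(m + 1):
        H[i, 0] = left_h[i]
        E[i, 0] = left_e[i]
        F[i, 0] = left_f[i]
    for i in range(1, m + 1):
        a = c0[i - 1]
        for j in range(1, n + 1):
            e = E[i, j - 1] - Ge
            eo = H[i, j - 1] - Go
            if eo > e:
                e = eo
            f = F[i - 1, j] - Ge
            fo = H[i - 1, j] - Go
            if fo > f:
                f = fo
            h = H[i - 1, j - 1] + pmat[a, c1[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if local and h < 0:
                h = 0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
    return H, E, F


@njit(cache=True)
def band_linear(c0, c1b, pmat, G, local, top_h, left_h, spec_idx):
    """Row-sweep fill of a column band, O(width) working memory.

    ``top_h``: boundary values of row 0 over the band's columns, index 0
    being the in-border column left of the band; ``left_h``: the in-border
    column values for rows 0..m.  Returns the band's right border column,
    the H special rows (over the band's own columns) and the band's best
    local cell (score, i, j-within-band); the best is meaningful in local
    mode only.
    """
    m = c0.shape[0]
    w = c1b.shape[0]
    prev = top_h.copy()
    cur = np.empty(w + 1, np.int64)
    out_h = np.empty(m + 1, np.int64)
    out_h[0] = top_h[w]
    spec_h = np.empty((spec_idx.shape[0], w), np.int64)
    best = np.int64(0)
    bi = np.int64(0)
    bj = np.int64(0)
    si = 0
    for i in range(1, m + 1):
        a = c0[i - 1]
        cur[0] = left_h[i]
        for t in range(1, w + 1):
            v = prev[t - 1] + pmat[a, c1b[t - 1]]
            u = prev[t] - G
            if u > v:
                v = u
            x = cur[t - 1] - G
            if x > v:
                v = x
            if local and v < 0:
                v = 0
            cur[t] = v
            if local and (
                v > best
                or (v == best and (i + t < bi + bj or (i + t == bi + bj and i < bi)))
            ):
                if v > 0:
                    best = v
                    bi = i
                    bj = t
        out_h[i] = cur[w]
        if si < spec_idx.shape[0] and spec_idx[si] == i:
            spec_h[si, :] = cur[1:]
            si += 1
        tmp = prev
        prev = cur
        cur = tmp
    return out_h, spec_h, best, bi, bj


@njit(cache=True)
def band_affine(c0, c1b, pmat, Go, Ge, local, top_h, top_f, left_h, left_e, spec_idx):
    """Affine counterpart of band_linear.

    Emits H and E on the right border (E is what a horizontal gap run needs
    to cross a column border exactly) and H and F special rows (F is what a
    vertical run needs to cross a row).  out_e[0] is left for the caller,
    E on row 0 being a pure boundary convention.
    """
    m = c0.shape[0]
    w = c1b.shape[0]
    prev_h = top_h.copy()
    prev_f = top_f.copy()
    cur_h = np.empty(w + 1, np.int64)
    cur_e = np.empty(w + 1, np.int64)
    cur_f = np.empty(w + 1, np.int64)
    out_h = np.empty(m + 1, np.int64)
    out_e = np.empty(m + 1, np.int64)
    out_h[0] = top_h[w]
    out_e[0] = NEG
    spec_h = np.empty((spec_idx.shape[0], w), np.int64)
    spec_f = np.empty((spec_idx.shape[0], w), np.int64)
    best = np.int64(0)
    bi = np.int64(0)
    bj = np.int64(0)
    si = 0
    for i in range(1, m + 1):
        a = c0[i - 1]
        cur_h[0] = left_h[i]
        cur_e[0] = left_e[i]
        cur_f[0] = NEG
        for t in range(1, w + 1):
            e = cur_e[t - 1] - Ge
            eo = cur_h[t - 1] - Go
            if eo > e:
                e = eo
            f = prev_f[t] - Ge
            fo = prev_h[t] - Go
            if fo > f:
                f = fo
            h = prev_h[t - 1] + pmat[a, c1b[t - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if local and h < 0:
                h = 0
            cur_e[t] = e
            cur_f[t] = f
            cur_h[t] = h
            if local and (
                h > best
                or (h == best and (i + t < bi + bj or (i + t == bi + bj and i < bi)))
            ):
                if h > 0:
                    best = h
                    bi = i
                    bj = t
        out_h[i] = cur_h[w]
        out_e[i] = cur_e[w]
        if si < spec_idx.shape[0] and spec_idx[si] == i:
            spec_h[si, :] = cur_h[1:]
            spec_f[si, :] = cur_f[1:]
            si += 1
        tmp = prev_h
        prev_h = cur_h
        cur_h = tmp
        tmp = prev_f
        prev_f = cur_f
        cur_f = tmp
    return out_h, out_e, spec_h, spec_f, best, bi, bj
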