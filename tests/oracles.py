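"""Independent plain-Python oracles for the DP kernels.

Deliberately shares no code with the package: straightforward dictionary
based recurrences and, at tiny sizes, exhaustive enumeration over all
alignment paths with column-by-column scoring.
"""

from itertools import product

BIG_NEG = float("-inf")


def col_score(top, bot, scheme):
    if top == "-" and bot == "-":
        raise ValueError("gap-gap column")
    if "-" not in (top, bot):
        if scheme.substitution_hook is not None:
            return scheme.substitution_hook(top, bot)
        return scheme.ma if (top == bot and top in "ACGT") else -scheme.mi


def score_columns(cols, scheme):
    """Column-sum score with per-run gap charging; independent recomputation."""
    total, run, side = 0, 0, None
    for top, bot in cols:
        s = "top" if top == "-" else ("bot" if bot == "-" else None)
        if s is None:
            if run:
                total -= _gap(run, scheme)
                run, side = 0, None
            total += col_score(top, bot, scheme)
        else:
            if run and s != side:
                total -= _gap(run, scheme)
                run = 0
            run += 1
            side = s
    if run:
        total -= _gap(run, scheme)
    return total


def _gap(x, scheme):
    if scheme.gap_model == "affine":
        return scheme.G_open + (x - 1) * scheme.G_ext
    return x * scheme.G


def dp_global_linear(a, b, scheme):
    m, n = len(a), len(b)
    G = scheme.G
    H = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        H[i][0] = -G * i
    for j in range(n + 1):
        H[0][j] = -G * j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            p = col_score(a[i - 1], b[j - 1], scheme)
            H[i][j] = max(H[i - 1][j - 1] + p, H[i - 1][j] - G, H[i][j - 1] - G)
    return H


def dp_local_linear(a, b, scheme):
    m, n = len(a), len(b)
    G = scheme.G
    H = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            p = col_score(a[i - 1], b[j - 1], scheme)
            H[i][j] = max(0, H[i - 1][j - 1] + p, H[i - 1][j] - G, H[i][j - 1] - G)
    return H


def dp_affine(a, b, scheme, local):
    m, n = len(a), len(b)
    Go, Ge = scheme.G_open, scheme.G_ext
    H = [[BIG_NEG] * (n + 1) for _ in range(m + 1)]
    E = [[BIG_NEG] * (n + 1) for _ in range(m + 1)]
    F = [[BIG_NEG] * (n + 1) for _ in range(m + 1)]
    H[0][0] = 0
    for j in range(1, n + 1):
        H[0][j] = 0 if local else -(Go + (j - 1) * Ge)
        E[0][j] = H[0][j] if not local else BIG_NEG
    for i in range(1, m + 1):
        H[i][0] = 0 if local else -(Go + (i - 1) * Ge)
        F[i][0] = H[i][0] if not local else BIG_NEG
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            p = col_score(a[i - 1], b[j - 1], scheme)
            E[i][j] = max(E[i][j - 1] - Ge, H[i][j - 1] - Go)
            F[i][j] = max(F[i - 1][j] - Ge, H[i - 1][j] - Go)
            H[i][j] = max(H[i - 1][j - 1] + p, E[i][j], F[i][j])
            if local:
                H[i][j] = max(H[i][j], 0)
    return H, E, F


def global_score(a, b, scheme):
    if scheme.gap_model == "linear":
        return dp_global_linear(a, b, scheme)[len(a)][len(b)]
    if len(a) == 0 and len(b) == 0:
        return 0
    return dp_affine(a, b, scheme, local=False)[0][len(a)][len(b)]


def local_score(a, b, scheme):
    if scheme.gap_model == "linear":
        H = dp_local_linear(a, b, scheme)
    else:
        H = dp_affine(a, b, scheme, local=True)[0]
    return max((v for row in H for v in row), default=0)


def enumerate_global(a, b, scheme):
    """Every global alignment as a column list (exponential; tiny only)."""
    out = []

    def rec(i, j, acc):
        if i == len(a) and j == len(b):
            out.append(list(acc))
            return
        if i < len(a) and j < len(b):
            acc.append((a[i], b[j]))
            rec(i + 1, j + 1, acc)
            acc.pop()
        if i < len(a):
            acc.append((a[i], "-"))
            rec(i + 1, j, acc)
            acc.pop()
        if j < len(b):
            acc.append(("-", b[j]))
            rec(i, j + 1, acc)
            acc.pop()

    rec(0, 0, [])
    return out


def exhaustive_global_best(a, b, scheme):
    return max(score_columns(c, scheme) for c in enumerate_global(a, b, scheme))


def exhaustive_local(a, b, scheme):
    """(best score, set of optimal column tuples) over all substring pairs."""
    best, argmax = 0, set()
    for i1, i2 in product(range(len(a) + 1), repeat=2):
        if i1 > i2:
            continue
        for j1, j2 in product(range(len(b) + 1), repeat=2):
            if j1 > j2:
                continue
            if i1 == i2 and j1 == j2:
                continue
            for cols in enumerate_global(a[i1:i2], b[j1:j2], scheme):
                # a local alignment never starts or ends with a gap column:
                # stripping it scores at least as well
                if cols and ("-" in cols[0] or "-" in cols[-1]):
                    continue
                s = score_columns(cols, scheme)
                if s > best:
                    best, argmax = s, {tuple(cols)}
                elif s == best and s > 0:
                    argmax.add(tuple(cols))
    return best, argmax
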