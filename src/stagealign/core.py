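"""Domain types shared by every stage of the aligner.

The aligner compares two DNA sequences S0 (length m) and S1 (length n) under
a match/mismatch/gap scoring scheme.  All scores are integers; mismatch and
gap penalties are stored as non-negative magnitudes and applied with a minus
sign.  DP matrices are (m+1) x (n+1): row 0 / column 0 are the empty-prefix
boundary and residue i of S0 labels row i (1-based), mirroring the usual
S[1..n] notation.  Reported alignment coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

DNA_ALPHABET = "ACGT"

#: sentinel for "minus infinity" in affine E/F boundary cells; far from the
#: int64 limit so repeated gap subtractions cannot wrap.
NEG = int(-(1 << 60))

# arrow bits shared by all kernels.  For the affine model UP marks provenance
# from the vertical-gap matrix F and LEFT from the horizontal-gap matrix E.
DIAG, UP, LEFT, STOP = 1, 2, 4, 8
# arrow bits inside the E/F gap matrices.
OPEN, EXT = 1, 2


class AlphabetError(ValueError):
    """A residue outside the normalized alphabet."""


class MalformedAlignmentError(ValueError):
    """An alignment violating its structural invariants, e.g. a (gap, gap) column."""


class WrongKernelError(TypeError):
    """A kernel invoked with the wrong gap model."""


class SizeGuardError(ValueError):
    """An exhaustive operation invoked beyond its guarded problem size."""


class DataflowError(ValueError):
    """Inconsistent messages between pipeline workers (border shape mismatch etc.)."""


class ConfigurationError(ValueError):
    """An invalid pipeline configuration."""


class CheckpointError(ValueError):
    """Corrupt or unusable special-row checkpoint data."""


class IntegrityError(ValueError):
    """Crosspoints inconsistent with the stored checkpoints."""


class ConcatenationError(ValueError):
    """Sub-alignments that do not join contiguously."""


class PlacementError(ValueError):
    """A decoy block that cannot be placed as requested."""


class FormatError(ValueError):
    """A malformed input or output file."""


@dataclass(frozen=True)
class Sequence:
    """A DNA sequence with an identifier.

    Residues are uppercased on construction.  Letters outside {A,C,G,T}
    (N and other IUPAC codes) are kept and score as a mismatch against
    everything, including themselves.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        norm = self.residues.upper()
        if norm and not norm.isalpha():
            bad = sorted({c for c in norm if not c.isalpha()})
            raise AlphabetError(f"non-letter residues {bad!r} in sequence {self.id!r}")
        object.__setattr__(self, "residues", norm)

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch values and the gap model.

    ``mi``, ``G``, ``G_open`` and ``G_ext`` are magnitudes (all >= 0) applied
    as penalties.  In the affine model a run of x gaps costs
    ``gamma(x) = G_open + (x-1) * G_ext`` with ``G_open >= G_ext``.
    ``substitution_hook(a, b) -> int`` overrides the ma/mi rule entirely.
    """

    ma: int = 1
    mi: int = 1
    gap_model: str = "linear"
    G: Optional[int] = None
    G_open: Optional[int] = None
    G_ext: Optional[int] = None
    substitution_hook: Optional[Callable[[str, str], int]] = None

    def __post_init__(self) -> None:
        if self.ma <= 0:
            raise ValueError("match value ma must be a positive integer")
        if self.mi < 0:
            raise ValueError("mismatch penalty magnitude mi must be >= 0")
        if self.gap_model == "linear":
            if self.G is None or self.G < 0:
                raise ValueError("linear gap model requires G >= 0")
        elif self.gap_model == "affine":
            if self.G_open is None or self.G_ext is None:
                raise ValueError("affine gap model requires G_open and G_ext")
            if not (self.G_open >= self.G_ext >= 0):
                raise ValueError("affine gap model requires G_open >= G_ext >= 0")
        else:
            raise ValueError(f"unknown gap model {self.gap_model!r}")

    @classmethod
    def linear(cls, ma: int = 1, mi: int = 1, G: int = 2, **kw) -> "ScoringScheme":
        return cls(ma=ma, mi=mi, gap_model="linear", G=G, **kw)

    @classmethod
    def affine(cls, ma: int = 1, mi: int = 1, G_open: int = 5, G_ext: int = 1, **kw) -> "ScoringScheme":
        return cls(ma=ma, mi=mi, gap_model="affine", G_open=G_open, G_ext=G_ext, **kw)

    @property
    def is_affine(self) -> bool:
        return self.gap_model == "affine"


def p_score(a: str, b: str, scheme: ScoringScheme) -> int:
    """Substitution score p(a, b): +ma on a match, -mi on a mismatch.

    The optional substitution hook takes precedence over ma/mi.  Residues
    outside {A,C,G,T} mismatch everything, including themselves.
    """
    for r in (a, b):
        if len(r) != 1 or not r.isalpha() or r != r.upper():
            raise AlphabetError(f"unnormalized residue {r!r}")
    if scheme.substitution_hook is not None:
        return int(scheme.substitution_hook(a, b))
    if a == b and a in DNA_ALPHABET:
        return scheme.ma
    return -scheme.mi


def gamma(x: int, scheme: ScoringScheme) -> int:
    """Penalty magnitude of one maximal gap run of length ``x`` (x >= 1).

    Affine: G_open + (x-1)*G_ext.  Linear: x*G, the degenerate case.
    """
    if x < 1:
        raise ValueError(f"gap-run length must be >= 1, got {x}")
    if scheme.is_affine:
        return scheme.G_open + (x - 1) * scheme.G_ext
    return x * scheme.G


Column = Tuple[str, str]


@dataclass
class Alignment:
    """A gapped pairwise alignment.

    ``columns`` pair a residue-or-'-' from S0 (top) with one from S1
    (bottom).  Coordinates are 1-based inclusive over the aligned region;
    an empty alignment has ``end = start - 1``.
    """

    columns: List[Column]
    score: int
    start0: int
    end0: int
    start1: int
    end1: int
    mode: str
    gap_model: str

    @classmethod
    def build(
        cls,
        columns: List[Column],
        scheme: ScoringScheme,
        mode: str,
        start0: int,
        start1: int,
    ) -> "Alignment":
        aln = cls(
            columns=list(columns),
            score=0,
            start0=start0,
            end0=start0 - 1 + sum(1 for t, _ in columns if t != "-"),
            start1=start1,
            end1=start1 - 1 + sum(1 for _, b in columns if b != "-"),
            mode=mode,
            gap_model=scheme.gap_model,
        )
        aln.score = score_alignment(aln, scheme)
        return aln

    @property
    def length(self) -> int:
        return len(self.columns)


def score_alignment(aln: Alignment, scheme: ScoringScheme) -> int:
    """Recompute an alignment's score from its columns.

    Matches/mismatches via p_score; gap runs charged gamma per maximal run
    (affine) or G per gap column (linear).  This is the consistency oracle:
    for every alignment the stored score must equal this recomputation.
    """
    total = 0
    run = 0  # length of the open gap run
    run_side = None  # 'top' or 'bottom'
    for top, bot in aln.columns:
        if top == "-" and bot == "-":
            raise MalformedAlignmentError("(gap, gap) column")
        side = "top" if top == "-" else ("bottom" if bot == "-" else None)
        if side is None:
            if run:
                total -= gamma(run, scheme)
                run, run_side = 0, None
            total += p_score(top, bot, scheme)
        else:
            if run and side != run_side:
                total -= gamma(run, scheme)
                run = 0
            run += 1
            run_side = side
    if run:
        total -= gamma(run, scheme)
    return total


@dataclass
class AlignmentStats:
    """Column-wise characterization of an alignment plus coverage."""

    length: int
    matches_pct: float
    mismatches_pct: float
    gaps_pct: float
    coverage_pct: float
    score: int


@dataclass
class DPMatrices:
    """Quadratic-space DP state: H (plus E/F for affine) with arrow provenance.

    Arrows are per-cell bitmasks: DIAG|UP|LEFT|STOP for H (UP/LEFT meaning
    "from F"/"from E" in the affine model) and OPEN|EXT for E and F.
    """

    H: np.ndarray
    mode: str
    arrows: np.ndarray
    E: Optional[np.ndarray] = None
    F: Optional[np.ndarray] = None
    arrows_e: Optional[np.ndarray] = None
    arrows_f: Optional[np.ndarray] = None

    @property
    def m(self) -> int:
        return self.H.shape[0] - 1

    @property
    def n(self) -> int:
        return self.H.shape[1] - 1


@dataclass
class MidpointVectors:
    """Forward/reverse last-row vectors of the divide-and-conquer midpoint."""

    CC: np.ndarray
    DD: np.ndarray
    RR: np.ndarray
    SS: np.ndarray
    i_star: int
    j_star: int


@dataclass(frozen=True)
class Partition:
    """A contiguous 1-based column range [j_lo, j_hi] owned by one worker."""

    index: int
    j_lo: int
    j_hi: int

    def __post_init__(self) -> None:
        if self.j_lo > self.j_hi:
            raise ConfigurationError(f"empty partition [{self.j_lo}, {self.j_hi}]")

    @property
    def width(self) -> int:
        return self.j_hi - self.j_lo + 1


@dataclass(eq=False)
class BorderColumn:
    """One full DP column exchanged between neighbouring workers.

    ``h`` (and ``e`` in the affine model) hold the monolithic matrix values
    of column ``j`` for rows 0..m.
    """

    partition_index: int
    j: int
    h: np.ndarray
    e: Optional[np.ndarray] = None


@dataclass(frozen=True)
class Crosspoint:
    """A cell where the optimal path crosses a partition border or special row.

    ``gap_state`` is True when the path crosses the border mid-gap-run: a
    horizontal (E) run for a column border, a vertical (F) run for a row.
    ``axis`` records which kind of border: 'col', 'row' or 'point' (a path
    endpoint).
    """

    i: int
    j: int
    score: Optional[int] = None
    gap_state: bool = False
    axis: str = "col"

    def same_location(self, other: "Crosspoint") -> bool:
        return (self.i, self.j, self.gap_state) == (other.i, other.j, other.gap_state)


@dataclass(eq=False)
class SpecialRows:
    """Checkpointed DP rows of one partition.

    ``rows`` maps a row index (multiples of the interval, plus row m) to the
    stored (H row, F row) restricted to the partition's columns j_lo..j_hi;
    F is None in the linear model.  ``path`` is the persistence handle once
    written to disk.
    """

    interval: int
    j_lo: int
    j_hi: int
    rows: Dict[int, Tuple[np.ndarray, Optional[np.ndarray]]]
    path: Optional[str] = None


@dataclass
class SpeculationRecord:
    """Outcome of one border-crosspoint speculation."""

    partition_index: int
    predicted: Crosspoint
    actual: Crosspoint
    cells_speculative: int = 0

    @property
    def hit(self) -> bool:
        return self.predicted.same_location(self.actual)


def pair_encoding(
    r0: str, r1: str, scheme: ScoringScheme
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integer-encode two residue strings and build their substitution matrix.

    Returns (codes0, codes1, pmat) where pmat[codes(a), codes(b)] == p_score.
    """
    alphabet = sorted(set(r0) | set(r1))
    index = {c: k for k, c in enumerate(alphabet)}
    c0 = np.fromiter((index[c] for c in r0), dtype=np.int64, count=len(r0))
    c1 = np.fromiter((index[c] for c in r1), dtype=np.int64, count=len(r1))
    size = max(1, len(alphabet))
    pmat = np.empty((size, size), dtype=np.int64)
    for a, ka in index.items():
        for b, kb in index.items():
            pmat[ka, kb] = p_score(a, b, scheme)
    return c0, c1, pmat
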