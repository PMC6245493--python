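"""The multi-worker staged aligner.

Stage 1 fills the DP matrix across W logical workers, each owning a
contiguous column range and forwarding its right border column to the next;
it yields the optimal score, the end cell, checkpointed special rows and the
saved border columns.  Stage 2 resolves, right to left, the crosspoints
where the optimal path crosses each partition border, either serially (PT)
or speculatively (IST: every worker starts tracing from its border's best
cell immediately and keeps the result only if the true crosspoint confirms
the guess).  Stage 3 refines the chain with the special-row crossings so
consecutive crosspoints are at most k rows apart; Stage 4 aligns each
bounded subproblem with the linear-space recursion; Stage 5 concatenates
and validates.

Workers are deterministic logical workers exchanging immutable messages;
outputs are byte-identical for every worker count and speculation mode.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import linear_space, reference, stats as stats_mod, wavefront
from .core import (
    NEG,
    Alignment,
    AlignmentStats,
    BorderColumn,
    ConcatenationError,
    ConfigurationError,
    Crosspoint,
    IntegrityError,
    Partition,
    ScoringScheme,
    SpecialRows,
    SpeculationRecord,
)
from .reference import SequenceLike, _residues

log = logging.getLogger("stagealign.pipeline")


def partition_columns(n: int, W: int) -> List[Partition]:
    """W contiguous column ranges tiling [1..n]; remainders go leftmost."""
    if W < 1 or W > n:
        raise ConfigurationError(f"need 1 <= workers <= n, got W={W}, n={n}")
    base, rem = divmod(n, W)
    parts = []
    lo = 1
    for p in range(W):
        width = base + (1 if p < rem else 0)
        parts.append(Partition(index=p, j_lo=lo, j_hi=lo + width - 1))
        lo += width
    return parts


@dataclass
class Stage1Result:
    """Everything later stages need, kept as immutable-by-convention messages."""

    r0: str
    r1: str
    scheme: ScoringScheme
    mode: str
    k: int
    partitions: List[Partition]
    specials: List[SpecialRows]
    left_borders: List[BorderColumn]  # left_borders[p] = column j_lo(p)-1; [W] = column n
    opt_score: int
    end_cell: Optional[Tuple[int, int]]

    @property
    def m(self) -> int:
        return len(self.r0)

    @property
    def n(self) -> int:
        return len(self.r1)

    @property
    def W(self) -> int:
        return len(self.partitions)

    def partition_of_column(self, j: int) -> int:
        for p in self.partitions:
            if p.j_lo <= j <= p.j_hi:
                return p.index
        raise ValueError(f"column {j} outside [1..{self.n}]")


def stage1(
    S0: SequenceLike,
    S1: SequenceLike,
    scheme: ScoringScheme,
    W: int = 1,
    k: Optional[int] = None,
    mode: str = "local",
) -> Stage1Result:
    """Distributed matrix fill: optimal score, end cell, specials and borders."""
    r0, r1 = _residues(S0), _residues(S1)
    m, n = len(r0), len(r1)
    if m < 1 or n < 1:
        raise ConfigurationError("stage1 requires non-empty sequences")
    if k is None:
        k = wavefront.default_special_interval(m)
    partitions = partition_columns(n, W)
    border = wavefront.boundary_border(m, scheme, mode)
    left_borders = [border]
    specials: List[SpecialRows] = []
    best: Tuple[int, Optional[Tuple[int, int]]] = (0, None)
    for part in partitions:
        border, spec, local_best = wavefront.band_fill(
            r0, r1, part, scheme, mode=mode, in_border=border, k=k
        )
        specials.append(spec)
        left_borders.append(border)
        if mode == "local" and local_best is not None and local_best[1] is not None:
            s, (bi, bj) = local_best
            cs, cell = best
            if s > cs or (
                s == cs
                and cell is not None
                and (bi + bj, bi) < (cell[0] + cell[1], cell[0])
            ) or (s > 0 and cell is None):
                best = (s, (bi, bj))
    if mode == "local":
        opt_score, end_cell = best
    else:
        opt_score, end_cell = int(left_borders[-1].h[m]), (m, n)
    return Stage1Result(
        r0=r0,
        r1=r1,
        scheme=scheme,
        mode=mode,
        k=k,
        partitions=partitions,
        specials=specials,
        left_borders=left_borders,
        opt_score=opt_score,
        end_cell=end_cell,
    )


def speculate_crosspoint(border: BorderColumn) -> Crosspoint:
    """Guess the crosspoint on a border column: its maximal H cell.

    Ties resolve to the smallest row; the gap state is guessed from whether
    the E value attains H there (the path would cross mid horizontal run).
    """
    i = int(np.argmax(border.h))
    gap = bool(border.e is not None and border.e[i] == border.h[i])
    return Crosspoint(i=i, j=border.j, score=int(border.h[i]), gap_state=gap, axis="col")


# ---------------------------------------------------------------------------
# partial traceback over checkpointed strips


def _strip_step_affine(dp, r_h, li, lj, st, local):
    """One bounded traceback over a strip; no columns, positions only."""
    H, aH, aE, aF = dp.H, dp.arrows, dp.arrows_e, dp.arrows_f
    from .core import DIAG, EXT, LEFT, OPEN, UP

    while True:
        if st == "H" and local and H[li, lj] == 0:
            return "start", li, lj, st
        if lj == 0:
            return "col", li, lj, st
        if li == 0:
            return "row", li, lj, st
        if st == "H":
            b = aH[li, lj]
            if b & DIAG:
                li -= 1
                lj -= 1
            elif b & LEFT:
                st = "E"
            elif b & UP:
                st = "F"
            else:
                raise IntegrityError(f"no arrow at strip H({li},{lj})")
        elif st == "E":
            b = aE[li, lj]
            lj -= 1
            st = "H" if b & OPEN else "E"
            if not b:
                raise IntegrityError("no arrow in strip E")
        else:
            b = aF[li, lj]
            li -= 1
            st = "H" if b & OPEN else "F"
            if not b:
                raise IntegrityError("no arrow in strip F")


def _strip_step_linear(H, arrows, li, lj, local):
    from .core import DIAG, LEFT, UP

    while True:
        if local and H[li, lj] == 0:
            return "start", li, lj, "H"
        if lj == 0:
            return "col", li, lj, "H"
        if li == 0:
            return "row", li, lj, "H"
        b = arrows[li, lj]
        if b & DIAG:
            li -= 1
            lj -= 1
        elif b & UP:
            li -= 1
        elif b & LEFT:
            lj -= 1
        else:
            raise IntegrityError(f"no arrow at strip ({li},{lj})")


def _walk_partition(
    res: Stage1Result,
    p: int,
    entry: Tuple[int, int, str],
    record: bool,
) -> Tuple[str, Crosspoint, List[Crosspoint], int]:
    """Trace the optimal path backwards through partition p.

    Recomputes the matrix strip between consecutive special rows (bounded by
    the stored border column on the left) and walks it, repeating upwards
    until the path leaves through the left border ('exit'), reaches the
    global origin ('start' in global mode) or stops at a zero cell ('start'
    in local mode).  Returns (kind, crosspoint, special-row crossings,
    cells recomputed).
    """
    part = res.partitions[p]
    scheme = res.scheme
    local = res.mode == "local"
    affine = scheme.is_affine
    in_b = res.left_borders[p]
    spec = res.specials[p]
    k = res.k
    i, j, st = entry
    crossings: List[Crosspoint] = []
    cells = 0
    while True:
        if j == part.j_lo - 1:
            if i == 0 and j == 0:
                return "start", Crosspoint(0, 0, axis="point"), crossings, cells
            return (
                "exit",
                Crosspoint(i, j, score=int(in_b.h[i]), gap_state=(st == "E"), axis="col"),
                crossings,
                cells,
            )
        if i == 0:
            if part.j_lo - 1 == 0:
                return "start", Crosspoint(0, 0, axis="point"), crossings, cells
            return (
                "exit",
                Crosspoint(
                    0, part.j_lo - 1, score=int(in_b.h[0]), gap_state=affine, axis="col"
                ),
                crossings,
                cells,
            )
        r_lo = ((i - 1) // k) * k
        width = j - (part.j_lo - 1)
        r0seg = res.r0[r_lo:i]
        r1seg = res.r1[part.j_lo - 1 : j]
        if r_lo == 0:
            row_h = wavefront._top_row(scheme, res.mode, part.j_lo - 1, j)
            row_f = np.full(width + 1, NEG, np.int64)
        else:
            h_row, f_row = spec.rows[r_lo]
            row_h = np.concatenate(([in_b.h[r_lo]], h_row[:width]))
            if affine:
                row_f = np.concatenate(([np.int64(NEG)], f_row[:width]))
        left_h = in_b.h[r_lo : i + 1]
        cells += len(r0seg) * width
        if affine:
            left_e = in_b.e[r_lo : i + 1]
            c0, c1, pmat = reference.pair_encoding(r0seg, r1seg, scheme)
            H, E, F = reference._run_fill_affine(
                c0, c1, pmat, scheme.G_open, scheme.G_ext, local,
                row_h, np.full(width + 1, NEG, np.int64), row_f,
                left_h, left_e, np.full(len(r0seg) + 1, NEG, np.int64),
            )
            aH, aE, aF = reference.arrows_affine(
                H, E, F, reference._pmatrix(c0, c1, pmat),
                scheme.G_open, scheme.G_ext, local,
            )
            dp = reference.DPMatrices(
                H=H, E=E, F=F, mode=res.mode, arrows=aH, arrows_e=aE, arrows_f=aF
            )
            kind, li, lj, st = _strip_step_affine(dp, row_h, i - r_lo, width, st, local)
        else:
            c0, c1, pmat = reference.pair_encoding(r0seg, r1seg, scheme)
            H = reference._run_fill_linear(c0, c1, pmat, scheme.G, local, row_h, left_h)
            arrows = reference.arrows_linear(
                H, reference._pmatrix(c0, c1, pmat), scheme.G, local
            )
            kind, li, lj, st = _strip_step_linear(H, arrows, i - r_lo, width, local)
        gi, gj = r_lo + li, (part.j_lo - 1) + lj
        if kind == "start":
            return "start", Crosspoint(gi, gj, axis="point"), crossings, cells
        if kind == "col":
            if gi == 0 and gj == 0:
                return "start", Crosspoint(0, 0, axis="point"), crossings, cells
            return (
                "exit",
                Crosspoint(
                    gi, part.j_lo - 1, score=int(in_b.h[gi]),
                    gap_state=(st == "E"), axis="col",
                ),
                crossings,
                cells,
            )
        # crossed special row r_lo; continue with the strip above
        if record and r_lo > 0:
            crossings.append(
                Crosspoint(r_lo, gj, gap_state=(st == "F"), axis="row")
            )
        i, j = r_lo, gj


@dataclass
class PartialTraceback:
    partition_index: int
    entry: Crosspoint
    result: Crosspoint
    cells: int


@dataclass
class Stage2Result:
    chain: List[Crosspoint]
    partials: Dict[int, PartialTraceback]
    records: List[SpeculationRecord] = field(default_factory=list)
    cells_traceback: int = 0
    cells_speculative: int = 0


def _entry_state(cp: Crosspoint) -> str:
    if not cp.gap_state:
        return "H"
    return "E" if cp.axis == "col" else "F"


def _resolve(res: Stage1Result, cached=None, predictions=None) -> Stage2Result:
    """Serial right-to-left crosspoint resolution (the PT dataflow).

    With ``cached``/``predictions`` (IST) a partition's speculative result is
    reused when the true entry confirms the predicted one.
    """
    out = Stage2Result(chain=[], partials={})
    if res.mode == "local" and (res.opt_score <= 0 or res.end_cell is None):
        return out
    ei, ej = res.end_cell
    end_cp = Crosspoint(ei, ej, score=res.opt_score, axis="point")
    sp = res.partition_of_column(ej)
    out.chain = [end_cp]
    entry_cp = end_cp
    for p in range(sp, -1, -1):
        entry = (entry_cp.i, entry_cp.j, _entry_state(entry_cp))
        reused = False
        if predictions is not None and p in predictions and p != sp:
            pred = predictions[p]
            rec = SpeculationRecord(
                partition_index=p,
                predicted=pred,
                actual=entry_cp,
                cells_speculative=cached[p][3] if p in cached else 0,
            )
            out.records.append(rec)
            if rec.hit:
                kind, cp, crossings, cells = cached[p]
                reused = True
        if not reused:
            kind, cp, crossings, cells = _walk_partition(res, p, entry, record=False)
            out.cells_traceback += cells
        out.partials[p] = PartialTraceback(p, entry_cp, cp, cells)
        out.chain.insert(0, cp)
        if kind == "start":
            break
        entry_cp = cp
        if p == 0:
            # exited through column 0 in global mode; the path head is the
            # vertical run from the origin
            if not (cp.i == 0 and cp.j == 0):
                out.chain.insert(0, Crosspoint(0, 0, axis="point"))
            break
    out.records.sort(key=lambda r: r.partition_index)
    return out


def stage2_pt(res: Stage1Result) -> Stage2Result:
    """Pipeline Traceback: serial crosspoint resolution, no speculation."""
    return _resolve(res)


def stage2_ist(res: Stage1Result) -> Stage2Result:
    """Incremental Speculative Traceback.

    Every partition with a saved right border starts tracing immediately
    from that border's best cell; the serial resolution then reuses a
    speculative result whenever the true entry crosspoint confirms the
    guess.  Speculation never changes the answer: the chain is identical to
    stage2_pt's on every input.
    """
    predictions: Dict[int, Crosspoint] = {}
    cached: Dict[int, tuple] = {}
    spec_cells = 0
    for p in range(res.W - 1):
        pred = speculate_crosspoint(res.left_borders[p + 1])
        predictions[p] = pred
        kind, cp, crossings, cells = _walk_partition(
            res, p, (pred.i, pred.j, _entry_state(pred)), record=False
        )
        cached[p] = (kind, cp, crossings, cells)
        spec_cells += cells
    out = _resolve(res, cached=cached, predictions=predictions)
    out.cells_speculative = spec_cells
    return out


def speculation_summary(records: List[SpeculationRecord]) -> Tuple[int, int, float]:
    """(hits, misses, hit ratio); an empty record list reports ratio 1.0."""
    hits = sum(1 for r in records if r.hit)
    misses = len(records) - hits
    ratio = 1.0 if not records else hits / len(records)
    return hits, misses, ratio


def stage3_split(
    res: Stage1Result,
    partition_index: int,
    entry_cp: Crosspoint,
    exit_cp: Crosspoint,
) -> List[Crosspoint]:
    """Crosspoints where the path crosses partition's stored special rows.

    Re-walks the partition between the Stage-2 entry and exit crosspoints
    and records each special-row crossing; consecutive crosspoints end up at
    most k rows apart.  Raises IntegrityError when the walk disagrees with
    the given exit (corrupt checkpoints).
    """
    entry = (entry_cp.i, entry_cp.j, _entry_state(entry_cp))
    kind, cp, crossings, _ = _walk_partition(res, partition_index, entry, record=True)
    ok = (
        cp.i == exit_cp.i
        and cp.j == exit_cp.j
        and cp.gap_state == exit_cp.gap_state
    )
    if not ok:
        raise IntegrityError(
            f"stage-3 walk of partition {partition_index} ended at "
            f"({cp.i},{cp.j},{cp.gap_state}), expected "
            f"({exit_cp.i},{exit_cp.j},{exit_cp.gap_state})"
        )
    return list(reversed(crossings))


def refine_chain(res: Stage1Result, chain: List[Crosspoint]) -> List[Crosspoint]:
    """Insert the Stage-3 special-row crossings into the Stage-2 chain."""
    if len(chain) < 2:
        return list(chain)
    affine = res.scheme.is_affine
    out = [chain[0]]
    for a, b in zip(chain, chain[1:]):
        if b.j == a.j:
            # degenerate vertical segment on a boundary column: split it at
            # the special-row pitch so crosspoint spacing stays <= k
            for r in range((a.i // res.k + 1) * res.k, b.i, res.k):
                out.append(Crosspoint(r, b.j, gap_state=affine, axis="row"))
        else:
            p = (
                res.partition_of_column(b.j)
                if b.axis == "point"
                else next(q.index for q in res.partitions if q.j_hi == b.j)
            )
            out.extend(stage3_split(res, p, b, a))
        out.append(b)
    return out


def stage4_balanced(
    res: Stage1Result,
    chain: List[Crosspoint],
    max_area: int = linear_space.DEFAULT_BASE_CASE_AREA,
) -> List[List[Tuple[str, str]]]:
    """Align each subproblem between consecutive crosspoints.

    Subproblems are independent (order-free); each runs the linear-space
    recursion down to direct DP at ``max_area``.  Gap states at the
    crosspoints become boundary conditions: the piece below/right of a
    mid-run crosspoint has its opening penalty waived, the piece above/left
    is forced to end inside the run, so every run is charged gamma once.
    """
    pieces = []
    for a, b in zip(chain, chain[1:]):
        r0seg = res.r0[a.i : b.i]
        r1seg = res.r1[a.j : b.j]
        start_gap = (
            ("E" if a.axis == "col" else "F") if a.gap_state else None
        )
        end_gap = ("E" if b.axis == "col" else "F") if b.gap_state else None
        pieces.append(
            linear_space.mm_align_segment(
                r0seg, r1seg, res.scheme, start_gap, end_gap, max_area
            )
        )
    return pieces


def stage5_concat(
    res: Stage1Result,
    chain: List[Crosspoint],
    pieces: List[List[Tuple[str, str]]],
) -> Alignment:
    """Concatenate the sub-alignments and validate against the Stage-1 score."""
    if len(pieces) != max(0, len(chain) - 1):
        raise ConcatenationError("piece count does not match the crosspoint chain")
    if not chain:
        return Alignment.build([], res.scheme, res.mode, 1, 1)
    columns: List[Tuple[str, str]] = []
    for (a, b), piece in zip(zip(chain, chain[1:]), pieces):
        top = sum(1 for t, _ in piece if t != "-")
        bot = sum(1 for _, u in piece if u != "-")
        if top != b.i - a.i or bot != b.j - a.j:
            raise ConcatenationError(
                f"piece between ({a.i},{a.j}) and ({b.i},{b.j}) spans "
                f"({top},{bot}) residues"
            )
        columns.extend(piece)
    start = chain[0]
    aln = Alignment.build(columns, res.scheme, res.mode, start.i + 1, start.j + 1)
    if aln.score != res.opt_score:
        raise ConcatenationError(
            f"concatenated score {aln.score} != stage-1 optimum {res.opt_score}"
        )
    return aln


@dataclass
class PipelineConfig:
    """Knobs of the staged aligner.

    ``speculation``: 'none' and 'pt' both run the serial Pipeline Traceback
    (PT is a scheduling overlap with no dataflow effect); 'ist' adds
    speculative tracebacks from border maxima.
    """

    mode: str = "local"
    workers: int = 1
    special_row_interval: Optional[int] = None
    speculation: str = "none"
    max_area: int = linear_space.DEFAULT_BASE_CASE_AREA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("global", "local"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.speculation not in ("none", "pt", "ist"):
            raise ConfigurationError(f"unknown speculation {self.speculation!r}")
        if self.workers < 1:
            raise ConfigurationError("workers must be >= 1")


@dataclass
class AlignResult:
    alignment: Alignment
    stats: AlignmentStats
    records: List[SpeculationRecord]
    report: Dict[str, object]


def _degenerate_alignment(r0: str, r1: str, scheme: ScoringScheme, mode: str) -> Alignment:
    if mode == "local":
        return Alignment.build([], scheme, "local", 1, 1)
    cols = [(a, "-") for a in r0] + [("-", b) for b in r1]
    return Alignment.build(cols, scheme, "global", 1, 1)


def align_full(
    S0: SequenceLike,
    S1: SequenceLike,
    scheme: ScoringScheme,
    config: Optional[PipelineConfig] = None,
) -> AlignResult:
    """Run all five stages end to end."""
    config = config or PipelineConfig()
    r0, r1 = _residues(S0), _residues(S1)
    m, n = len(r0), len(r1)
    report: Dict[str, object] = {
        "mode": config.mode,
        "gap_model": scheme.gap_model,
        "workers": config.workers,
        "speculation": config.speculation,
        "cells_stage1": m * n,
        "petacells": stats_mod.petacells(max(m, 1), max(n, 1)) if m and n else 0.0,
    }
    if m == 0 or n == 0:
        aln = _degenerate_alignment(r0, r1, scheme, config.mode)
        return AlignResult(
            alignment=aln,
            stats=stats_mod.alignment_stats(aln, m, n),
            records=[],
            report=report,
        )
    res = stage1(
        r0, r1, scheme, W=config.workers, k=config.special_row_interval, mode=config.mode
    )
    report["special_row_interval"] = res.k
    report["opt_score"] = res.opt_score
    log.info("stage 1 done: opt_score=%d end_cell=%s W=%d k=%d",
             res.opt_score, res.end_cell, res.W, res.k)
    if config.mode == "local" and res.opt_score <= 0:
        aln = Alignment.build([], scheme, "local", 1, 1)
        return AlignResult(
            alignment=aln,
            stats=stats_mod.alignment_stats(aln, m, n),
            records=[],
            report=report,
        )
    s2 = stage2_ist(res) if config.speculation == "ist" else stage2_pt(res)
    log.info("stage 2 done (%s): %d border crosspoints",
             "IST" if config.speculation == "ist" else "PT", max(0, len(s2.chain) - 2))
    chain = refine_chain(res, s2.chain)
    log.info("stage 3 done: %d crosspoints", len(chain))
    pieces = stage4_balanced(res, chain, config.max_area)
    log.info("stage 4 done: %d subproblems", len(pieces))
    aln = stage5_concat(res, chain, pieces)
    log.info("stage 5 done: score=%d length=%d", aln.score, aln.length)
    hits, misses, ratio = speculation_summary(s2.records)
    report.update(
        cells_traceback=s2.cells_traceback,
        cells_speculative=s2.cells_speculative,
        speculation_hits=hits,
        speculation_misses=misses,
        speculation_hit_ratio=ratio,
        crosspoints=len(chain),
    )
    return AlignResult(
        alignment=aln,
        stats=stats_mod.alignment_stats(aln, m, n),
        records=s2.records,
        report=report,
    )
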