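# stagealign

Exact pairwise alignment of long DNA sequences with a staged, partitioned
engine: the classical quadratic-space dynamic-programming kernels, a
linear-memory divide-and-conquer traceback, and a multi-worker pipeline with
speculative traceback, all on a plain CPU.

## Who this is for

Comparing two chromosome-scale DNA sequences *exactly* (no seeding
heuristics) means filling a dynamic-programming matrix with `m x n` cells —
petacells for mammalian chromosomes — and then recovering the optimal
alignment path. Production systems split that work across accelerators by
column ranges and reconstruct the traceback from checkpoints. `stagealign`
implements that whole algorithmic stack as a portable, testable library:
researchers get bit-exact reference kernels to validate against, and the
partitioned pipeline demonstrates (and lets you measure) the dataflow —
border-column exchange, special-row checkpoints, crosspoint speculation — at
desk scale.

## The algorithms

For sequences `S0` (length `m`) and `S1` (length `n`) and integer scores
`+ma` (match), `-mi` (mismatch):

* **Global alignment** (Needleman–Wunsch): `H[i][j] = max(H[i-1][j-1] +
  p(i,j), H[i-1][j] - G, H[i][j-1] - G)` with boundary `H[i][0] = -G*i`,
  `H[0][j] = -G*j`; optimum at `H[m][n]`.
* **Local alignment** (Smith–Waterman): the same recurrence with a fourth
  `0` branch and zero boundaries; negative cells are not allowed, the
  optimum is the matrix maximum, and traceback stops at a zero cell.
* **Affine gaps** (Gotoh): a run of `x` gaps costs `gamma(x) = G_open +
  (x-1)*G_ext`, tracked with three matrices `H`, `E` (gaps in `S0`) and `F`
  (gaps in `S1`).
* **Linear space** (Hirschberg / Myers–Miller): forward and reverse
  last-row vectors meet at a midpoint on an optimal path; the problem splits
  there and recurses. With affine gaps, a second constrained vector pair
  (`DD`/`SS`) finds midpoints inside gap runs and the junction is corrected
  by `+(G_open - G_ext)` so the run is charged once.
* **Wavefront evaluation**: cells on an anti-diagonal are mutually
  independent; the band engine computes any column range in O(width) memory
  given the border column to its left, emitting border columns, special-row
  checkpoints and the band maximum.
* **Staged pipeline**: Stage 1 fills the matrix across W workers (optimal
  score); Stage 2 resolves the crosspoints where the optimal path crosses
  each partition border, serially (PT) or speculatively from each border's
  maximum (IST — a miss is recomputed, so speculation never changes the
  result); Stage 3 splits partitions at special rows; Stage 4 aligns each
  bounded subproblem in linear space; Stage 5 concatenates and validates.

Alignment statistics (match/mismatch/gap percentages, coverage), petacell
and GCUPS accounting, and the energy/break-even arithmetic for speculative
execution are in `stagealign.stats`.

## Worked example

The two 12-mers `TATAGGTAGCTA` and `GAGCTATGAGGT` under match +1,
mismatch −1, gap −2 have two co-optimal local alignments, both with score 5:

```python
>>> from stagealign import ScoringScheme, sw_align, enumerate_optimal_local
>>> scheme = ScoringScheme.linear(ma=1, mi=1, G=2)
>>> sw_align("TATAGGTAGCTA", "GAGCTATGAGGT", scheme).score
5
>>> for a in enumerate_optimal_local("TATAGGTAGCTA", "GAGCTATGAGGT", scheme):
...     print("".join(t for t, _ in a.columns), "/", "".join(b for _, b in a.columns))
TAT-AGGT / TATGAGGT
AGCTA / AGCTA
```

The same comparison through the two-worker pipeline from the shell:

```
$ stagealign --query q.fa --target t.fa --workers 2 --speculation ist \
             --out aln.fa --stats-out stats.tsv
INFO stagealign: aligning q (m=12) vs t (n=12), mode=local, linear gaps
INFO stagealign.pipeline: stage 1 done: opt_score=5 end_cell=(12, 6) W=2 k=1
INFO stagealign.pipeline: stage 2 done (IST): 0 border crosspoints
INFO stagealign.pipeline: stage 3 done: 6 crosspoints
INFO stagealign.pipeline: stage 4 done: 5 subproblems
INFO stagealign.pipeline: stage 5 done: score=5 length=5
INFO stagealign: score=5 length=5; speculation hits=0 misses=0 ratio=1.00
$ cat aln.fa
>q start=8 end=12 mode=local gap_model=linear score=5
AGCTA
>t start=2 end=6
AGCTA
$ cat stats.tsv
Score   5
Length  5
Coverage        41.7%
Matches 100.0%
Mismatches      0.0%
Gaps    0.0%
```

The traceback picks the `AGCTA` variant (best-cell ties resolve to the
smallest `i+j`); the stats say the 5 aligned columns are all matches and
cover 41.7% of the two sequences on average (5/12 of each). Zero border
crosspoints is expected here: the optimal region sits inside one worker's
columns.

Synthetic homologous pairs for larger experiments come from the built-in
generator (`stagealign.synth.generate_homolog_pair`), which mutates a random
ancestor with substitutions and geometric-length indels and keeps the exact
edit record.

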