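# Methods

## Model and conventions

All kernels maximize an integer similarity score. Mismatch and gap
parameters are stored as non-negative magnitudes (`mi`, `G`, `G_open`,
`G_ext`) and applied as penalties; a printed scheme "+1 / −1 / −2" is
`ma=1, mi=1, G=2`. The DP grid is `(m+1) x (n+1)` with row 0 / column 0 as
the empty-prefix boundary; residue `i` of `S0` labels row `i`. Reported
alignment coordinates are 1-based inclusive, with `end = start - 1` for an
empty alignment, so `end - start + 1` always equals the number of aligned
residues.

Letters outside `{A,C,G,T}` (N and the other IUPAC codes) are kept,
uppercased, and scored as a mismatch against everything **including
themselves** — the conservative choice that can only lower a score, never
inflate it. The substitution hook (`scheme.substitution_hook(a, b) -> int`)
replaces the match/mismatch rule entirely when set; it exists so a
protein-style scoring matrix can be plugged in, but no matrix file parser is
provided (DNA is the target domain).

The affine model is standard Gotoh in score-maximization form: `E` carries
runs of gaps in `S0` (horizontal moves, consuming `S1`), `F` runs of gaps in
`S1` (vertical moves), `H = max(H_diag + p, E, F)` with a fourth `0` branch
**only** in local mode. A run of length `x` costs `gamma(x) = G_open +
(x-1) * G_ext` exactly once, which fixes the boundary conventions:
`E[i][0] = F[0][j] = -inf`, `E[0][j] = H[0][j] = -gamma(j)` and symmetrically
for column 0 in global mode. `G_open = G_ext = G` reproduces the linear
kernel cell for cell (tested).

## Tie-breaks and determinism

Every operation is deterministic. The fixed choices are:

* traceback in `H`: diagonal, then the horizontal branch for linear gaps
  (up before left); diagonal, then `E`, then `F` for affine gaps;
* inside `E`/`F`: close the run (OPEN) before extending it;
* local best cell: smallest `i+j`, then smallest `i`;
* divide-and-conquer midpoint: smallest `j*`, preferring the match-state
  branch over the in-gap branch at equal `j*`;
* border-crosspoint speculation: smallest row among border maxima.

These are conventions, not claims: co-optimal alignments exist and
`enumerate_optimal_local` materializes all of them at toy scale
(`m*n <= 1e5` guarded).

## Linear-space recursion and gap states

The divide-and-conquer computes forward last-row vectors `CC` (best score)
and `DD` (best score ending in a vertical gap) to the middle row, and their
reverse counterparts `RR`/`SS`, in O(n) memory. Only vertical runs can span
a row boundary, so the midpoint either sits in the match state
(`CC(j) + RR(n-j)`) or inside a vertical run (`DD(j) + SS(n-j) + G_open -
G_ext`). The junction constant is forced by the gap function: a run of
length `x = x1 + x2` split across the boundary is charged `gamma(x1) +
gamma(x2) = gamma(x) + (G_open - G_ext)` by the two constrained vectors, so
exactly `G_open - G_ext` must be added back. (Under the alternative gap
convention `g + h*x` the same constant is the opening cost `g`.) The test
suite pins this down by requiring the achieved midpoint maximum to equal the
full-matrix optimum on hundreds of random pairs.

When a split point lies inside a run, the left child is **forced** to end in
the gap state (its optimum is read from `F`, resp. `E`) and the right child
gets the opening penalty of a leading run on that axis **waived** (boundary
`H[i][0] = F[i][0] = -i * G_ext`). Forcing one side and waiving the other is
what makes concatenation exact: any pair of child optima then corresponds to
a real path charged `gamma` once per run. The same mechanism joins pipeline
subproblems at crosspoints, and the final score is always recomputed from
the concatenated columns and compared with the Stage-1 optimum — a
structural self-check that fails loudly rather than silently.

Base cases (area ≤ `base_case_area`, default 4096 cells — small enough that
a quadratic fill is microseconds, large enough that recursion overhead stays
negligible) run the full quadratic kernel with the same boundary flags.
Local mode first locates the optimal end cell with a forward O(n)-memory
sweep and the start cell with a reverse sweep, then aligns the bounded
rectangle globally.

## Band engine and the staged pipeline

The band engine evaluates a column range given the true border column to its
left, sweeping rows with two working rows. Row sweep and anti-diagonal sweep
have the same dependency structure (`antidiagonal_schedule` exposes the
wavefront order explicitly and the tests check it partitions the grid in
dependency order); the observable contract is bit-exact integer equality
with the monolithic fill, which the suite asserts for border columns and
special rows on randomized partitions.

Exactness across boundaries dictates what crosses them: a **column** border
carries `H` and `E` (a horizontal run may span it), a checkpointed **row**
carries `H` and `F` (a vertical run may span it). Special rows are stored
every `k` rows plus row `m`; the default `k = ceil(m/100)` keeps checkpoint
memory near 1% of the matrix while bounding every traceback strip to `k`
rows. Crosspoints carry `(i, j, gap_state)`, where `gap_state` marks a
border crossed mid-run; after Stage 3 consecutive crosspoints are at most
`k` rows apart (degenerate boundary-column segments are split at the same
pitch so the bound is unconditional).

Stage 2's partial traceback never stores alignment columns: it recomputes
the strip between consecutive special rows (left-bounded by the stored
border column), walks it, and keeps only positions and states. Stage 4 then
re-derives each bounded subproblem's columns with the linear-space
recursion, and Stage 5 validates contiguity and the total score.

Workers are deterministic logical workers exchanging immutable messages; the
concurrency of a real multi-device run is a scheduling overlay with no
effect on the dataflow, which is why `speculation="pt"` and `"none"` produce
identical results (PT only overlaps stages in time) and why outputs are
byte-identical for every worker count.

IST speculates on **all** saved borders at once: each partition traces from
its border's maximum immediately, and the serial resolution reuses the
cached result on a confirmed guess. On a miss the speculative traceback is
discarded wholesale — the simplest policy that preserves exactness — and the
wasted cells are accounted in the run report so the energy/break-even
arithmetic in `stats` has inputs. An empty record list reports a hit ratio
of 1.0 (vacuous success). The speculation heuristic is exact whenever the
border maximum is unique and on-path, which is the overwhelmingly common
case for high-similarity sequences; the test suite also constructs the
opposite case (a planted decoy repeat pulling a border maximum off-path) and
checks the miss is detected and absorbed.

## Synthetic data

`generate_homolog_pair` mutates a uniform-random ancestor with independent
substitutions (default regime used in tests: 3–5%) and geometric-length
indels (insertions and deletions equiprobable), recording every event. This
reproduces what the pipeline actually cares about in homologous-chromosome
comparisons — high identity, clustered gaps, a dominant near-diagonal
optimal path — and deliberately nothing else: no repeat families, no GC or
isochore structure, no rearrangements. Tests passing on these pairs
demonstrate dataflow exactness and speculation behaviour, not robustness to
repeat-rich biology; `plant_decoy_repeat` adds the one repeat feature that
matters to speculation (an off-path high-similarity copy). Generation is
fully reproducible from the seed.

## Numerics and problem sizes

All scores are int64; "minus infinity" boundary cells use a sentinel of
`-2^60`, far enough from the int64 limit that any realistic chain of gap
subtractions cannot wrap. There is no floating point anywhere in the
kernels, so equality assertions in the tests are exact.

The suite exercises randomized pairs up to length 600 (200 pairs for the
oracle-equivalence property, with all of: both gap models, local and global
modes, 1–4 workers, checkpoint intervals from 1 to m) and synthetic
homolog pairs up to 5000 x 4800; these sizes make every property checkable
against full quadratic matrices while the whole suite stays in the
tens-of-seconds range. Inner loops are numba-jitted, so the first call in a
fresh environment pays a few seconds of compilation.

## Known limitations

* No block pruning or banding: every cell is computed, even where the
  optimum cannot pass.
* Logical workers are sequential; the library models the dataflow, not
  wall-clock parallel speedup.
* The energy/cost functions are pure arithmetic over caller-supplied
  measurements; nothing here measures power.
* Output formats are gapped FASTA and a per-column TSV; pairwise
  whole-chromosome alignment has no read/reference asymmetry, so SAM/MAF
  emitters are out of scope.
* `enumerate_optimal_local` is exhaustive by design and guarded at
  `m*n <= 1e5`.
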