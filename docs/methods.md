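# Methods

## Mutation model

The generative engine is a 20-state Markov chain over the amino acids. The
one-step matrix `PAM1` is derived from the embedded Dayhoff (1978)
accepted-point-mutation exchangeabilities `s_ij` and equilibrium
frequencies `π` (both shipped as plain text under `src/alnbench/data/`):
`Q_ij = s_ij·π_j` with the diagonal set so rows sum to zero, and
`PAM1 = expm(t·Q)` with `t` solved (Brent's method, tolerance 1e-14) so
that the expected fraction of sites changing in one step,
`1 − Σ_i π_i·PAM1_ii`, is exactly 1%. The chain is reversible with
stationary distribution `π`, so simulated sequences keep the Dayhoff
composition at every distance, and the identity between two descendants
diverged for `n` steps each equals the ancestor-descendant identity at
`2n` — the classical equivalence between the "diverging" and "sequential"
schemes. The resulting identity-vs-distance curve reproduces the standard
correspondence (75% at 30 PAM, 20% at ~250 PAM).

`expected_identity` gives closed forms for both schemes
(`Σ π_i (PAM1^n)_ii` and `Σ_i π_i Σ_a (PAM1^n)_ia²`); the simulator is
validated against them.

## Scoring matrices

Package `PAM250` is the original Dayhoff one-decimal log-odds matrix on the
conventional `10·log10` scale (it rounds to the familiar NCBI integer
PAM250 within one unit everywhere). The fractional dialect is retained
because the two published calibration constants this package checks itself
against — the mean random substitution weight (−0.863) and the length-10
random-alignment density (−0.858) — match the fractional matrix
(−0.868 / ≈−0.866 computed) and not the integer one (−0.844 / ≈−0.842).
`Gonnet250` is the Gonnet–Cohen–Benner 1992 matrix at its native
`10·log10` scale; the 10 / 0.5 penalties used with it are on that scale.
Both tables are loaded from Biopython's canonical collection and re-indexed
to the alphabetical residue order `ARNDCQEGHILKMFPSTWYV`; NCBI-style square
text matrices can be read and written for custom scoring
(`substitution.read_matrix` / `write_matrix`). `make_log_odds` derives
PAM-n matrices from the mutation model for the matrix-sensitivity sweep.

## Sequence simulation

Parameters and defaults, chosen to represent the study conditions:

| parameter | default | meaning |
|---|---|---|
| `ancestor_length` | 200 | residues in the ancestor (fixed, not "about") |
| `pam` | — | PAM1 cycles per branch; one grid uses 30/60/120/240 |
| `p_del` | 0.55 | probability an indel event is a deletion |
| `zipf_exponent` | 1.5 | indel-length law `P(k) ∝ k^−a` |
| `max_indel_len` | 50 | truncation of the length law |
| `r` | grid | total console length / ancestor length |
| `c` | grid | console asymmetry |

The indel pass scans ancestor positions 1..L+1 left to right (L+1 admits
insertions only). At each position an event occurs with probability
`0.0224 − 0.0219·e^(−0.01168·PAM)`; it is a deletion with probability
0.55, else an insertion placed *before* the position. Events are discarded
whole when they would overrun the terminus, start on an already-deleted
site, or start exactly where an earlier indel ended (which would silently
elongate it); realized lengths therefore follow the drawn law. Point
mutations then resample every *ancestor-derived* site from the PAM1 row of
its current residue, for exactly `pam` cycles; inserted residues never
mutate. Console residues are i.i.d. background, generated per the length
formulas `T = round(200·r)`, shorter console `round(T·(1−c)/2)` (left on
S1, right on S2), longer `T − shorter` — at `r = 0.1, c = 0.1` this gives
the 9/11/11/9 split used throughout as the geometry sanity check.

The indel-length exponent is not published; it was calibrated once so that
the simulated fraction of indel columns in the gold-standard alignment
matches the reported calibration table at 30 PAM (3.3% ancestor-descendant,
6.6% descendant-descendant; exponent 1.5 reproduces both, 1.7 gives
2.65%/5.2%). The two cores of a pair are *not* coupled in total indel
length; each branch draws independently.

Randomness: one `numpy.random.Generator` per test set; the per-pair draw
order (ancestor; branch 1 indel scan — occurrence, type, length, insertion
residues — then one uniform vector per mutation cycle; branch 2; consoles
L1, R1, L2, R2) is fixed and part of the reproducibility contract. Grid
runs derive per-cell seeds as `SeedSequence(master, spawn_key=(cell_index,))`.

## Aligners

Gotoh three-state dynamic programming (match / gap-in-S2 / gap-in-S1),
numba-compiled, floating-point scores throughout. A gap of length `g`
costs `GOP + GEP·g` — the open penalty is charged *in addition to* the
first extension, a convention pinned by the console-overhang bookkeeping
`2·GEP·L_con·c + 2·GOP` in the density model; tools differ here, so it is
stated prominently. Global alignments penalize end gaps in full; the local
variant floors at the empty alignment (score 0). Ties are broken
deterministically (match > gap-in-S2 > gap-in-S1; among co-optimal local
fragments, the lexicographically smallest end coordinates win). Scores are
verified against exhaustive enumeration on every sequence pair up to
length 5 over a toy alphabet and against an independent affine-gap
implementation (Biopython's `PairwiseAligner`) on random protein-like
pairs.

## Quality evaluation

`Accuracy = I/G` and `Confidence = I/A` per pair, where A counts
algorithmic match columns with at least one core residue — console-console
matches carry no information about the gold standard and are excluded.
Set-level numbers are unweighted per-pair means in percent (pooled counts
differ by <0.5% at n = 1000). A pair whose local alignment vanished
(A = 0) contributes zero to both means: an alignment that disappeared
restored nothing, and treating it as missing data would inflate the
collapse-regime numbers.

## Density model and slope zone

`Score_glob(c) = L_ker·D_ker + L_con·D_con·(1−c) − 2·GEP·L_con·c − 2·GOP`,
`D_glob(c) = Score_glob(c)/(L_ker + L_con)`, and the predicted collapse
asymmetry `c*` solves the linear equation `D_glob(c) = D_rand` exactly.
Estimation choices, all Monte-Carlo from the package's own primitives:

- `D_ker` — mean substitution weight of the gold-standard match columns
  divided by the mean core length. Indel columns are deliberately **not**
  charged gap penalties here: the quantity the model needs is the
  recoverable signal the reference carries per core residue. Charging
  affine costs for every unmatched run (an alternative the API still
  offers) drives `D_ker` at 120 PAM from ≈1.0 down to ≈0.23 and pushes the
  predicted `c*` far below the asymmetry where global accuracy actually
  collapses, breaking the model's defining property.
- `D_con` — density of globally aligning two random sequences of
  console-total length `L_con` (the scale at which console-on-console
  alignment happens).
- `D_rand` — the same at full sequence length `L_ker + L_con`.

The empirical slope zone used for validation is the two-grid-interval
window (20% wide on the standard 0–1 grid in steps of 0.1) with the
steepest total accuracy drop; the predicted `c*` falls inside it for all
four validated (PAM, r) combinations (30/120 × 100%/200%).

## Problem sizes and numerical choices

The full 224-set × 1000-pair design is supported and deterministic;
routine validation runs the identity calibration at 1000 pairs per set,
quality cells at 200–300 pairs (per-pair accuracy SD is ~20% in the
collapse regime, giving set-level SEs of ~1.5%), the length-10 density at
10⁵ pairs (SE ≈ 0.003 on a value of ≈−0.866), and density-model fits at
200–300 alignment repetitions per term. Degenerate inputs are rejected
with explicit errors (empty sequences, empty test sets, non-normalized
backgrounds, `c` outside [0, 1], zero denominator in `c*`); `PAM1` rows
are renormalized after the matrix exponential so long matrix powers stay
stochastic.

## What the simulator does and does not capture

Simulated data are homogeneous in time and across sites: every position
mutates under the same PAM1 chain, indel rates are position-independent,
and consoles are pure noise. Real proteins violate all three —
conserved motifs, hydrophobic cores, compositional bias, domain shuffling
— so absolute accuracies here are optimistic upper bounds, and the
global-vs-local crossover point on real sequences will shift with local
conservation structure. What does transfer is the mechanism: global
alignment fails once the true alignment's score density falls to the
random-alignment baseline, and the affine-in-`c` model locates that point
from measurable quantities. Gumbel-statistics of local scores,
nucleotide models, and block-based aligners for intermittent similarity
are out of scope.
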