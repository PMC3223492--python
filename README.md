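# alnbench

**When should you trust a global protein alignment, and when should you
switch to a local one?** `alnbench` answers this the only way it can be
answered rigorously: on sequences whose *true* alignment is known. It
simulates pairs of amino-acid sequences descending from a common ancestor —
so the gold-standard (evolutionary) alignment is known by construction —
aligns them with global and local affine-gap aligners, measures how much of
the truth each recovers, and provides an analytic model that predicts where
global alignment collapses.

The package is aimed at method developers and benchmark builders in sequence
analysis who need gold-standard-aware test data and a quantitative criterion
for the global-vs-local choice.

## The model in brief

**Simulation.** An ancestor P of 200 residues is drawn i.i.d. from the
Dayhoff amino-acid frequencies. Two *cores* K1, K2 evolve independently
from P: an indel pass (per-position indel probability
`0.0224 − 0.0219·e^(−0.01168·PAM)`, deletions with probability 0.55,
Zipf-distributed lengths) followed by `PAM` cycles of PAM1 point-mutation
resampling. Each core is flanked by unrelated random *consoles*; their
total length is `r·|P|` per sequence and their left/right split is
controlled by the asymmetry `c ∈ [0, 1]` (the shorter console sits left on
S1 and right on S2, so large `c` shifts the cores in opposite directions).
The gold standard pairs exactly the positions that descend from the same
ancestor site.

**Alignment.** Gotoh dynamic programming, gap cost `GOP + GEP·g` for a gap
of length `g`. Global: PAM250, GOP 14, GEP 2, end gaps penalized. Local:
Gonnet250, GOP 10, GEP 0.5.

**Quality.** With G gold-standard match columns, A assessed algorithmic
match columns (both residues present, at least one in a core) and I columns
common to both: `Accuracy = I/G`, `Confidence = I/A`.

**Collapse prediction.** The expected gold-standard score of a global
alignment is affine in `c`:

    Score_glob(c) = L_ker·D_ker + L_con·D_con·(1−c) − 2·GEP·L_con·c − 2·GOP

Dividing by the sequence length gives a density `D_glob(c)`; global
alignment degrades sharply near the root `c*` of `D_glob(c) = D_rand`,
where `D_rand` is the density of optimally aligning two *random* sequences
of the same length — past `c*`, the true alignment scores no better than
noise and cannot be recovered.

## Worked example

```python
import alnbench as ab

model = ab.dayhoff_model()
pam250 = ab.load_matrix("PAM250")
gonnet = ab.load_matrix("Gonnet250")

# 100 pairs at 120 PAM per branch, consoles as long as the core (r = 1.0),
# strongly asymmetric (c = 0.7): the adversarial regime for global alignment
ts = ab.generate_test_set(ab.EvolParams(pam=120), ab.ConsoleSpec(r=1.0, c=0.7),
                          model, n_pairs=100, seed=42)

for mode, matrix, gap in [("global", pam250, ab.GapPenalty(14, 2)),
                          ("local", gonnet, ab.GapPenalty(10, 0.5))]:
    align = ab.align_global if mode == "global" else ab.align_local
    results = [ab.evaluate_pair(align(p.s1, p.s2, matrix, gap), p) for p in ts]
    acc, conf = ab.aggregate(results)
    print(f"{mode:6s} accuracy {acc:5.2f}%  confidence {conf:5.2f}%")

id_dd, indel_dd = ab.reference_stats(ts, "descendant_descendant")
print(f"gold standard: {id_dd:.1f}% identity, {indel_dd:.1f}% indel columns")
```

prints

```
global accuracy  0.00%  confidence  0.00%
local  accuracy 69.02%  confidence 67.10%
gold standard: 21.4% identity, 16.7% indel columns
```

The cores share only ~21% identity and sit at opposite ends of their
sequences; the global aligner, forced to span the mismatched consoles,
recovers *nothing* of the true alignment, while the local aligner still
restores about 69% of it. At symmetric consoles (`c = 0`) the ordering
reverses — the global aligner is consistently the better one.

The same machinery is scriptable from the shell:

```bash
$ alnbench slope-zone --pam 30 --r 1.0 --n-pairs 100 --seed 7
...
0.8     90.88
0.9     63.53
1       16.63
# predicted c* = 0.966
# empirical slope zone = [0.8, 1]
```

— the analytically predicted collapse asymmetry lands inside the window
where measured accuracy actually plunges. `alnbench align`,
`alnbench density` and `alnbench sweep` cover single alignments, the
random-density curve, and full quality sweeps (TSV out).

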