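"""Analytic model of where global alignment collapses ("slope zone").

As console asymmetry ``c`` grows, a global alignment must bridge the
oppositely shifted cores with ever longer end gaps.  The expected score of
the gold-standard global alignment is affine in ``c``::

    Score_glob(c) = L_ker*D_ker + L_con*D_con*(1-c) - 2*GEP*L_con*c - 2*GOP

where L_ker, D_ker are mean core length and per-residue score of the
reference core alignment, L_con the total console length per sequence, and
D_con the per-residue score of aligning unrelated random sequence at console
scale.  Dividing by the sequence length L_ker + L_con gives the density
D_glob(c).  Global alignment quality collapses near the asymmetry where this
density meets the density D_rand of optimally aligning two *random*
sequences of the same length: past that point the true alignment scores no
better than noise and cannot be recovered.  The crossing is the root of the
linear equation D_glob(c) = D_rand, available in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aligners import GapPenalty, align_global
from .evolver import TestSet
from .substitution import ScoringMatrix


@dataclass(frozen=True)
class DensityParams:
    """Inputs of the density model (score units per residue, lengths in residues)."""

    L_ker: float
    D_ker: float
    L_con: float
    D_con: float
    D_rand: float
    gop: float
    gep: float

    def __post_init__(self) -> None:
        if self.L_ker <= 0 or self.L_con < 0:
            raise ValueError("lengths must be positive")


def score_glob(c: float, p: DensityParams) -> float:
    """Expected gold-standard global score at console asymmetry ``c``."""
    if not 0.0 <= c <= 1.0:
        raise ValueError("c must be in [0, 1]")
    return (p.L_ker * p.D_ker + p.L_con * p.D_con * (1.0 - c)
            - 2.0 * p.gep * p.L_con * c - 2.0 * p.gop)


def d_glob(c: float, p: DensityParams) -> float:
    """Gold-standard alignment density: score_glob(c) / (L_ker + L_con)."""
    return score_glob(c, p) / (p.L_ker + p.L_con)


def critical_asymmetry(p: DensityParams) -> float | None:
    """Root of D_glob(c) = D_rand; None when it falls outside [0, 1].

    The equation is linear in ``c``, so the root is exact:
    c* = [L_ker*D_ker + L_con*D_con - 2*GOP - D_rand*(L_ker+L_con)]
         / [L_con*(D_con + 2*GEP)].
    """
    denom = p.L_con * (p.D_con + 2.0 * p.gep)
    if denom == 0.0:
        raise ZeroDivisionError("degenerate model: L_con*(D_con + 2*GEP) = 0")
    c = (p.L_ker * p.D_ker + p.L_con * p.D_con - 2.0 * p.gop
         - p.D_rand * (p.L_ker + p.L_con)) / denom
    return c if 0.0 <= c <= 1.0 else None


def estimate_density_curve(lengths: list[int], matrix: ScoringMatrix,
                           gap: GapPenalty, n_reps: int,
                           rng: np.random.Generator,
                           background: np.ndarray) -> list[tuple[int, float]]:
    """Mean density of global alignment of random sequence pairs per length."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not lengths:
        raise ValueError("lengths must be non-empty")
    out = []
    for length in lengths:
        if length < 1:
            raise ValueError("lengths must be positive")
        draws = rng.choice(20, size=(n_reps, 2, length),
                           p=background).astype(np.uint8)
        total = 0.0
        for k in range(n_reps):
            total += align_global(draws[k, 0], draws[k, 1], matrix, gap).score
        out.append((length, total / n_reps / length))
    return out


def reference_core_score(pair, matrix: ScoringMatrix,
                         gap: GapPenalty | None = None) -> float:
    """Score of the gold-standard alignment of the two cores.

    Match columns contribute substitution weights.  By default indel columns
    are not charged: the density model asks how much recoverable signal the
    reference carries per core residue, and charging affine penalties for
    every unmatched run drives the predicted collapse far below where global
    alignment actually degrades.  Pass ``gap`` to charge maximal runs of
    unmatched core positions as gaps with the aligner's GOP/GEP convention.
    """
    ref = pair.reference
    s = float(matrix.scores[pair.s1[ref[:, 0]], pair.s2[ref[:, 1]]].sum()) \
        if len(ref) else 0.0
    if gap is not None:
        for (lo, hi), col in ((pair.core1, 0), (pair.core2, 1)):
            bounds = np.concatenate([[lo - 1], ref[:, col], [hi]])
            run_lengths = np.diff(bounds) - 1
            for g in run_lengths[run_lengths > 0]:
                s -= gap.cost(int(g))
    return s


def estimate_core_density(ts: TestSet, matrix: ScoringMatrix,
                          gap: GapPenalty | None = None) -> float:
    """Mean per-residue score of the gold-standard core alignments in a set.

    Per pair: reference core score divided by the mean core length; the
    set-level density is the per-pair mean.  See
    :func:`reference_core_score` for the (default) gap-free convention.
    """
    if ts.n_pairs == 0:
        raise ValueError("empty test set")
    densities = []
    for pair in ts.pairs:
        len1 = pair.core1[1] - pair.core1[0]
        len2 = pair.core2[1] - pair.core2[0]
        mean_len = (len1 + len2) / 2.0
        densities.append(reference_core_score(pair, matrix, gap) / mean_len)
    return float(np.mean(densities))


def estimate_params(ts: TestSet, matrix: ScoringMatrix, gap: GapPenalty,
                    rng: np.random.Generator, n_reps: int = 200) -> DensityParams:
    """Fit all density-model inputs from a simulated test set.

    D_con is measured at console-length scale, D_rand at full sequence
    length (core plus consoles), both by Monte-Carlo global alignment of
    random background sequences.
    """
    from .substitution import dayhoff_model

    lker = float(np.mean([((p.core1[1] - p.core1[0]) + (p.core2[1] - p.core2[0])) / 2.0
                          for p in ts.pairs]))
    dker = estimate_core_density(ts, matrix)
    lcon = float(np.mean([len(p.s1) - (p.core1[1] - p.core1[0]) for p in ts.pairs]))
    bg = dayhoff_model().background
    if lcon > 0:
        (_, dcon), = estimate_density_curve([max(1, round(lcon))], matrix, gap,
                                            n_reps, rng, bg)
    else:
        dcon = 0.0
    (_, drand), = estimate_density_curve([max(1, round(lker + lcon))], matrix,
                                         gap, n_reps, rng, bg)
    return DensityParams(L_ker=lker, D_ker=dker, L_con=lcon, D_con=dcon,
                         D_rand=drand, gop=gap.gop, gep=gap.gep)


def locate_slope_zone(c_values: np.ndarray, accuracies: np.ndarray,
                      width: int = 2) -> tuple[float, float]:
    """Empirical slope zone: the ``width``-interval window of the c grid with
    the steepest total accuracy drop.

    On the standard 0, 0.1, ..., 1.0 grid the default width of two intervals
    matches the observed ~20%-wide collapse range.  Returns the window
    endpoints, against which the predicted c* is validated.
    """
    c_values = np.asarray(c_values, dtype=float)
    accuracies = np.asarray(accuracies, dtype=float)
    if len(c_values) < 2 or len(c_values) != len(accuracies):
        raise ValueError("need matching grids with at least two points")
    drops = np.diff(accuracies)
    width = min(width, len(drops))
    windows = [drops[k:k + width].sum() for k in range(len(drops) - width + 1)]
    k = int(np.argmin(windows))  # most negative total drop
    return float(c_values[k]), float(c_values[k + width])
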