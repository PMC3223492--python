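"""Orchestration of the benchmark experiments at configurable scale.

The full design crosses evolutionary distance (PAM), relative console
length (r) and console asymmetry (c): with the default grids this
enumerates 224 distinct test-set configurations (console-free sets exist
once per PAM, not once per c).  Each cell generates an independent test
set, aligns every pair with both the global and the local aligner, and
reports mean Accuracy/Confidence.

Determinism: every cell derives its own seed from the master seed via
``SeedSequence(master, spawn_key=(cell_index,))`` where ``cell_index`` is
the cell's position in the enumerated grid; two runs with the same master
seed and grid are identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np
import pandas as pd

from . import evaluator, slope_zone
from .aligners import GapPenalty, align_global, align_local
from .evolver import ConsoleSpec, EvolParams, TestSet, generate_test_set
from .substitution import dayhoff_model, load_matrix

DEFAULT_PAM = (30, 60, 120, 240)
DEFAULT_R = (0.0, 0.1, 0.2, 0.5, 1.0, 2.0)
DEFAULT_C = tuple(round(0.1 * k, 1) for k in range(11))


@dataclass(frozen=True)
class AlignerSettings:
    matrix: str
    gop: float
    gep: float

    @property
    def gap(self) -> GapPenalty:
        return GapPenalty(self.gop, self.gep)


@dataclass(frozen=True)
class SweepConfig:
    pam_values: Sequence[int] = DEFAULT_PAM
    r_values: Sequence[float] = DEFAULT_R
    c_values: Sequence[float] = DEFAULT_C
    n_pairs: int = 1000
    seed: int = 0
    global_aligner: AlignerSettings = AlignerSettings("PAM250", 14.0, 2.0)
    local_aligner: AlignerSettings = AlignerSettings("Gonnet250", 10.0, 0.5)
    zipf_exponent: float = 1.5
    max_indel_len: int = 50
    ancestor_length: int = 200

    def cells(self) -> list[tuple[int, float, float]]:
        """Enumerate distinct (pam, r, c) cells; r = 0 appears once per PAM."""
        out = []
        for pam in self.pam_values:
            for r in self.r_values:
                if r == 0:
                    out.append((pam, 0.0, 0.0))
                else:
                    for c in self.c_values:
                        out.append((pam, r, c))
        return out

    def evol_params(self, pam: int) -> EvolParams:
        return EvolParams(pam=pam, zipf_exponent=self.zipf_exponent,
                          max_indel_len=self.max_indel_len,
                          ancestor_length=self.ancestor_length)


def cell_seed(master_seed: int, cell_index: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(cell_index,))
    return int(ss.generate_state(1)[0] % 2**31)


def _evaluate_set(ts: TestSet, settings: AlignerSettings, mode: str
                  ) -> tuple[float, float]:
    matrix = load_matrix(settings.matrix)
    align = align_global if mode == "global" else align_local
    results = [evaluator.evaluate_pair(align(p.s1, p.s2, matrix, settings.gap), p)
               for p in ts.pairs]
    return evaluator.aggregate(results)


def run_quality_sweep(cfg: SweepConfig, out: IO[str] | None = None
                      ) -> pd.DataFrame:
    """Accuracy/Confidence of both aligners over the (PAM, r, c) grid.

    One row per (cell, mode).  When ``out`` is given, rows are flushed as
    each cell completes so long sweeps are resumable by cell key.
    """
    model = dayhoff_model()
    rows = []
    header_written = False
    for idx, (pam, r, c) in enumerate(cfg.cells()):
        ts = generate_test_set(cfg.evol_params(pam), ConsoleSpec(r=r, c=c),
                               model, cfg.n_pairs, cell_seed(cfg.seed, idx))
        for mode, settings in (("global", cfg.global_aligner),
                               ("local", cfg.local_aligner)):
            acc, conf = _evaluate_set(ts, settings, mode)
            rows.append(dict(pam=pam, r=r, c=c, mode=mode, n_pairs=cfg.n_pairs,
                             accuracy=acc, confidence=conf))
            if out is not None:
                row = rows[-1]
                if not header_written:
                    out.write("\t".join(row) + "\n")
                    header_written = True
                out.write("\t".join(str(v) for v in row.values()) + "\n")
                out.flush()
    return pd.DataFrame(rows)


def run_matrix_sweep(pam_values: Sequence[int], matrices: Sequence[str],
                     gop_values: Sequence[float], gep_values: Sequence[float],
                     n_pairs: int, seed: int,
                     zipf_exponent: float = 1.5) -> pd.DataFrame:
    """Global-alignment quality across scoring matrices and penalty grids.

    Test sets follow the sequential (ancestor vs descendant) scheme without
    consoles, so the grid isolates the effect of matrix/penalty choice.
    """
    if not pam_values or not matrices or not gop_values or not gep_values:
        raise ValueError("all parameter ranges must be non-empty")
    model = dayhoff_model()
    rows = []
    for idx, pam in enumerate(pam_values):
        params = EvolParams(pam=pam, zipf_exponent=zipf_exponent)
        ts = generate_test_set(params, ConsoleSpec(r=0.0, c=0.0), model,
                               n_pairs, cell_seed(seed, idx),
                               scheme="ancestor_descendant")
        for name in matrices:
            matrix = load_matrix(name)
            for gop in gop_values:
                for gep in gep_values:
                    gap = GapPenalty(gop, gep)
                    results = [evaluator.evaluate_pair(
                        align_global(p.s1, p.s2, matrix, gap), p)
                        for p in ts.pairs]
                    acc, conf = evaluator.aggregate(results)
                    rows.append(dict(pam=pam, matrix=name, gop=gop, gep=gep,
                                     accuracy=acc, confidence=conf))
    return pd.DataFrame(rows)


def run_density_experiment(lengths: Sequence[int], n_reps: int, seed: int,
                           matrix_name: str = "PAM250",
                           gop: float = 14.0, gep: float = 2.0) -> pd.DataFrame:
    """Random-alignment density versus sequence length."""
    if not lengths:
        raise ValueError("lengths must be non-empty")
    rng = np.random.default_rng(seed)
    curve = slope_zone.estimate_density_curve(
        list(lengths), load_matrix(matrix_name), GapPenalty(gop, gep),
        n_reps, rng, dayhoff_model().background)
    return pd.DataFrame(curve, columns=["length", "density"])


def run_slope_experiment(pam: int, r: float, n_pairs: int, seed: int,
                         c_values: Sequence[float] = DEFAULT_C,
                         n_density_reps: int = 200,
                         zipf_exponent: float = 1.5) -> dict:
    """Predicted collapse asymmetry c* versus the empirical slope zone.

    Runs a global-alignment accuracy sweep over the ``c`` grid, fits the
    density model on the symmetric-console set, and reports both the
    closed-form root and the empirically located steepest-drop interval.
    """
    model = dayhoff_model()
    matrix = load_matrix("PAM250")
    gap = GapPenalty(14.0, 2.0)
    params = EvolParams(pam=pam, zipf_exponent=zipf_exponent)
    accs = []
    first_set: TestSet | None = None
    for idx, c in enumerate(c_values):
        ts = generate_test_set(params, ConsoleSpec(r=r, c=c), model, n_pairs,
                               cell_seed(seed, idx))
        if first_set is None:
            first_set = ts
        results = [evaluator.evaluate_pair(align_global(p.s1, p.s2, matrix, gap), p)
                   for p in ts.pairs]
        acc, _ = evaluator.aggregate(results)
        accs.append(acc)
    rng = np.random.default_rng(cell_seed(seed, len(list(c_values))))
    dp = slope_zone.estimate_params(first_set, matrix, gap, rng,
                                    n_reps=n_density_reps)
    c_star = slope_zone.critical_asymmetry(dp)
    zone = slope_zone.locate_slope_zone(np.asarray(c_values), np.asarray(accs))
    return dict(pam=pam, r=r, c_values=list(c_values), accuracy=accs,
                density_params=dp, c_star=c_star, slope_zone=zone)
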