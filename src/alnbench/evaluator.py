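"""Alignment quality against the gold standard: Accuracy and Confidence.

Let G be the number of match columns in the gold-standard alignment, A the
number of assessed match columns in the algorithmic alignment (those with a
residue from both sequences, at least one of which lies in a core), and I
the number of columns common to both.  Then::

    Accuracy   = I / G   (how much of the truth was recovered)
    Confidence = I / A   (how much of the output is correct)

Console-vs-console match columns are excluded from A because console
positions are unaligned in the gold standard and say nothing about it.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import nan
from typing import Iterable

import numpy as np

from .aligners import GAP, PairwiseAlignment
from .evolver import TestPair


@dataclass(frozen=True)
class QualityResult:
    """Counts G, A, I and the derived quality ratios for one pair."""

    G: int
    A: int
    I: int

    def __post_init__(self) -> None:
        if not 0 <= self.I <= min(self.G, self.A):
            raise ValueError("need 0 <= I <= min(G, A)")

    @property
    def accuracy(self) -> float:
        """I/G, or NaN when the gold standard has no match columns."""
        return self.I / self.G if self.G else nan

    @property
    def confidence(self) -> float:
        """I/A, or NaN when no algorithmic columns were assessed."""
        return self.I / self.A if self.A else nan


def quality_from_counts(G: int, A: int, I: int) -> QualityResult:
    return QualityResult(G=G, A=A, I=I)


def evaluate_pair(algorithmic: PairwiseAlignment, pair: TestPair) -> QualityResult:
    """Score an algorithmic alignment of ``pair.s1`` vs ``pair.s2``."""
    cols = algorithmic.columns
    if len(cols):
        if cols[:, 0].max() >= len(pair.s1) or cols[:, 1].max() >= len(pair.s2):
            raise ValueError("alignment coordinates out of sequence range")
    both = cols[(cols[:, 0] != GAP) & (cols[:, 1] != GAP)]
    in_core1 = (both[:, 0] >= pair.core1[0]) & (both[:, 0] < pair.core1[1])
    in_core2 = (both[:, 1] >= pair.core2[0]) & (both[:, 1] < pair.core2[1])
    assessed = both[in_core1 | in_core2]
    # match columns as scalar keys for set intersection
    width = len(pair.s2) + 1
    algo_keys = assessed[:, 0] * width + assessed[:, 1]
    ref_keys = pair.reference[:, 0] * width + pair.reference[:, 1]
    common = np.intersect1d(algo_keys, ref_keys, assume_unique=True)
    return QualityResult(G=len(pair.reference), A=len(assessed), I=len(common))


def aggregate(results: Iterable[QualityResult]) -> tuple[float, float]:
    """Unweighted per-pair mean accuracy and confidence, in percent.

    A pair whose algorithmic alignment vanished (A = 0) restores nothing and
    contributes 0 to both means.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to aggregate")
    accs = [r.accuracy if r.G else 0.0 for r in results]
    confs = [r.confidence if r.A else 0.0 for r in results]
    return 100.0 * float(np.mean(accs)), 100.0 * float(np.mean(confs))
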