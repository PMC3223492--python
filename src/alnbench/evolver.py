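"""Simulation of homologous sequence pairs with known gold-standard alignments.

A test pair is built from a random Bernoulli ancestor: two "cores" evolve
independently from it (first an indel pass, then repeated PAM1 point-mutation
cycles), and each core is flanked by unrelated random "consoles".  Because
every surviving core position remembers which ancestor position it came from,
the true (gold-standard) alignment between the two sequences is known by
construction: it pairs exactly the positions descending from the same
ancestor site.  Console positions are unaligned by definition.

Console geometry is controlled by two ratios: ``r`` — total console length
relative to the ancestor length (equal for both sequences) — and ``c`` —
asymmetry between the left and right console.  Sequence 1 carries the shorter
console on the left, sequence 2 on the right, so at large ``c`` the cores are
shifted in opposite directions.

Indels occur per ancestor position with a rate that saturates with
evolutionary distance::

    P_indel(PAM) = 0.0224 - 0.0219 * exp(-0.01168 * PAM)

An event is a deletion with probability ``p_del`` (default 0.55), else an
insertion; lengths follow a truncated Zipf law.  Events that would overrun
the sequence end, start on an already-deleted site, or extend an earlier
indel are discarded whole, so realized indel lengths follow the drawn law.

All randomness flows through a single ``numpy.random.Generator`` per test
set.  The draw order per pair is fixed and part of the reproducibility
contract: ancestor residues; branch 1 (indel scan left to right: occurrence,
then type, then length, then insertion residues; then one uniform vector per
mutation cycle); branch 2 likewise; consoles L1, R1, L2, R2.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, Literal

import numpy as np

from .substitution import MutationModel, decode

Scheme = Literal["ancestor_descendant", "descendant_descendant"]

#: Constants of the indel-rate law (probability per ancestor position).
INDEL_RATE_SATURATION = 0.0224
INDEL_RATE_AMPLITUDE = 0.0219
INDEL_RATE_DECAY = 0.01168


@dataclass(frozen=True)
class EvolParams:
    """Parameters of one evolutionary branch (ancestor -> core)."""

    pam: int
    p_del: float = 0.55
    zipf_exponent: float = 1.5
    max_indel_len: int = 50
    ancestor_length: int = 200

    def __post_init__(self) -> None:
        if self.pam < 0:
            raise ValueError("pam must be >= 0")
        if not 0.0 < self.p_del < 1.0:
            raise ValueError("p_del must be in (0, 1)")
        if self.zipf_exponent <= 1.0:
            raise ValueError("zipf_exponent must be > 1")
        if self.max_indel_len < 1 or self.ancestor_length < 1:
            raise ValueError("lengths must be positive")


@dataclass(frozen=True)
class ConsoleSpec:
    """Console geometry: total relative length ``r``, asymmetry ``c``."""

    r: float
    c: float

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("r must be >= 0")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("c must be in [0, 1]")


@dataclass
class CoreTrace:
    """An evolved core plus the ancestry of each of its positions.

    ``origin[k]`` is the 0-based ancestor index that position ``k`` descends
    from, or -1 for inserted positions.  Surviving ancestor indices are
    strictly increasing along the core.
    """

    core: np.ndarray
    origin: np.ndarray

    @property
    def sequence(self) -> str:
        return decode(self.core)


@dataclass
class TestPair:
    """Two console-flanked sequences with their gold-standard alignment.

    ``reference`` is an (n, 2) array of full-sequence position pairs (0-based,
    strictly increasing in both columns); ``core1``/``core2`` are half-open
    index ranges of the cores within ``s1``/``s2``.
    """

    s1: np.ndarray
    s2: np.ndarray
    core1: tuple[int, int]
    core2: tuple[int, int]
    reference: np.ndarray
    ancestor: np.ndarray
    trace1: CoreTrace
    trace2: CoreTrace

    @property
    def seq1(self) -> str:
        return decode(self.s1)

    @property
    def seq2(self) -> str:
        return decode(self.s2)


@dataclass
class TestSet:
    pairs: list[TestPair]
    params: EvolParams
    spec: ConsoleSpec
    seed: int | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[TestPair]:
        return iter(self.pairs)


def generate_ancestor(length: int, background: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw an i.i.d. residue sequence from the background composition."""
    if length < 1:
        raise ValueError("length must be >= 1")
    background = np.asarray(background, dtype=float)
    if not np.isclose(background.sum(), 1.0, atol=1e-6):
        raise ValueError("background must sum to 1")
    return rng.choice(len(background), size=length, p=background).astype(np.uint8)


def indel_probability(pam: float) -> float:
    """Per-position indel probability at evolutionary distance ``pam``."""
    return INDEL_RATE_SATURATION - INDEL_RATE_AMPLITUDE * np.exp(-INDEL_RATE_DECAY * pam)


@lru_cache(maxsize=8)
def _zipf_cdf(exponent: float, max_len: int) -> np.ndarray:
    k = np.arange(1, max_len + 1, dtype=float)
    w = k ** (-exponent)
    return np.cumsum(w / w.sum())


def sample_indel_length(params: EvolParams, rng: np.random.Generator) -> int:
    """Draw an indel length from the truncated Zipf law P(k) ~ k^-a."""
    cdf = _zipf_cdf(params.zipf_exponent, params.max_indel_len)
    return int(np.searchsorted(cdf, rng.random(), side="right")) + 1


def apply_indels(ancestor: np.ndarray, params: EvolParams,
                 rng: np.random.Generator,
                 background: np.ndarray | None = None,
                 rate: float | None = None) -> CoreTrace:
    """First evolution stage: scan positions 1..L+1 and place indels.

    Position L+1 admits insertions only (the sequence terminus).  Discard
    rules: a deletion that would overrun the terminus or that starts on an
    already-deleted site is ignored; an insertion whose start coincides with
    the elongation of an earlier accepted indel is ignored.
    """
    if len(ancestor) == 0:
        raise ValueError("ancestor must be non-empty")
    L = len(ancestor)
    p = indel_probability(params.pam) if rate is None else rate
    deleted = np.zeros(L + 2, dtype=bool)  # 1-based positions 1..L
    insertions: dict[int, np.ndarray] = {}
    forbidden_ins: set[int] = set()
    for i in range(1, L + 2):
        if rng.random() >= p:
            continue
        if rng.random() < params.p_del:  # deletion starting at position i
            length = sample_indel_length(params, rng)
            if i + length - 1 > L or deleted[i]:
                continue
            deleted[i:i + length] = True
            forbidden_ins.add(i + length)
        else:  # insertion before position i
            length = sample_indel_length(params, rng)
            if i in forbidden_ins:
                continue
            if background is None:
                raise ValueError("background required to compose insertions")
            insertions[i] = rng.choice(len(background), size=length,
                                       p=background).astype(np.uint8)
            forbidden_ins.add(i)
    core: list[int] = []
    origin: list[int] = []
    for i in range(1, L + 2):
        if i in insertions:
            core.extend(insertions[i])
            origin.extend([-1] * len(insertions[i]))
        if i <= L and not deleted[i]:
            core.append(int(ancestor[i - 1]))
            origin.append(i - 1)
    return CoreTrace(core=np.array(core, dtype=np.uint8),
                     origin=np.array(origin, dtype=np.int64))


def apply_point_mutations(trace: CoreTrace, model: MutationModel, cycles: int,
                          rng: np.random.Generator) -> CoreTrace:
    """Second evolution stage: ``cycles`` rounds of PAM1 resampling.

    Only ancestor-derived sites mutate; inserted residues keep their original
    letters, and the ancestry records are unchanged.
    """
    mask = trace.origin >= 0
    sites = trace.core[mask].astype(np.int64)
    cdf = np.cumsum(model.pam1, axis=1)
    cdf[:, -1] = 1.0
    for _ in range(cycles):
        u = rng.random(len(sites))
        sites = (cdf[sites] > u[:, None]).argmax(axis=1)
    core = trace.core.copy()
    core[mask] = sites.astype(np.uint8)
    return CoreTrace(core=core, origin=trace.origin.copy())


def console_lengths(ancestor_length: int, spec: ConsoleSpec
                    ) -> tuple[int, int, int, int]:
    """Console lengths (l1, r1, l2, r2) for the two sequences.

    Total console length T = round(|P| * r); the shorter console is
    round(T*(1-c)/2) and sits left on sequence 1, right on sequence 2.
    """
    total = int(np.floor(ancestor_length * spec.r + 0.5))
    shorter = int(np.floor(total * (1.0 - spec.c) / 2.0 + 0.5))
    longer = total - shorter
    return shorter, longer, longer, shorter


def _evolve_branch(ancestor: np.ndarray, params: EvolParams,
                   model: MutationModel, rng: np.random.Generator) -> CoreTrace:
    trace = apply_indels(ancestor, params, rng, background=model.background)
    return apply_point_mutations(trace, model, params.pam, rng)


def compose_reference(origin1: np.ndarray, origin2: np.ndarray,
                      offset1: int = 0, offset2: int = 0) -> np.ndarray:
    """Gold-standard match columns: core positions sharing an ancestor site."""
    valid1 = np.nonzero(origin1 >= 0)[0]
    valid2 = np.nonzero(origin2 >= 0)[0]
    _, a, b = np.intersect1d(origin1[valid1], origin2[valid2],
                             return_indices=True)
    ref = np.column_stack([valid1[np.sort(a)] + offset1,
                           valid2[np.sort(b)] + offset2])
    return ref.astype(np.int64)


def build_test_pair(ancestor: np.ndarray, params: EvolParams,
                    spec: ConsoleSpec, model: MutationModel,
                    rng: np.random.Generator,
                    scheme: Scheme = "descendant_descendant") -> TestPair:
    """Evolve two cores from ``ancestor``, attach consoles, compose the
    gold standard.

    Under the sequential (``ancestor_descendant``) scheme the first sequence
    keeps the unmutated ancestor as its core and only branch 2 evolves.
    """
    if scheme == "ancestor_descendant":
        trace1 = CoreTrace(core=ancestor.copy(),
                           origin=np.arange(len(ancestor), dtype=np.int64))
    elif scheme == "descendant_descendant":
        trace1 = _evolve_branch(ancestor, params, model, rng)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    trace2 = _evolve_branch(ancestor, params, model, rng)

    l1, r1, l2, r2 = console_lengths(len(ancestor), spec)
    bg = model.background
    flanks = [rng.choice(len(bg), size=n, p=bg).astype(np.uint8)
              for n in (l1, r1, l2, r2)]
    s1 = np.concatenate([flanks[0], trace1.core, flanks[1]])
    s2 = np.concatenate([flanks[2], trace2.core, flanks[3]])
    reference = compose_reference(trace1.origin, trace2.origin, l1, l2)
    return TestPair(s1=s1, s2=s2,
                    core1=(l1, l1 + len(trace1.core)),
                    core2=(l2, l2 + len(trace2.core)),
                    reference=reference, ancestor=ancestor,
                    trace1=trace1, trace2=trace2)


def generate_test_set(params: EvolParams, spec: ConsoleSpec,
                      model: MutationModel, n_pairs: int, seed: int,
                      scheme: Scheme = "descendant_descendant") -> TestSet:
    """Generate ``n_pairs`` independent test pairs, reproducible from ``seed``."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_pairs):
        ancestor = generate_ancestor(params.ancestor_length, model.background, rng)
        pairs.append(build_test_pair(ancestor, params, spec, model, rng,
                                     scheme=scheme))
    return TestSet(pairs=pairs, params=params, spec=spec, seed=seed)


def reference_stats(ts: TestSet, scheme: Scheme) -> tuple[float, float]:
    """Mean (%id, %indel) of the gold-standard alignments in a test set.

    %id is the fraction of residue-identical columns among match columns;
    %indel is the fraction of gap columns among all reference-alignment
    columns (match columns plus unmatched core/ancestor positions; console
    positions contribute nothing).  Both are per-pair means in percent.
    """
    if ts.n_pairs == 0:
        raise ValueError("empty test set")
    ids: list[float] = []
    indels: list[float] = []
    for pair in ts.pairs:
        if scheme == "ancestor_descendant":
            for trace in (pair.trace1, pair.trace2):
                mask = trace.origin >= 0
                n_match = int(mask.sum())
                same = trace.core[mask] == pair.ancestor[trace.origin[mask]]
                gaps = (len(pair.ancestor) - n_match) + (len(trace.core) - n_match)
                ids.append(same.mean() if n_match else 0.0)
                indels.append(gaps / (n_match + gaps))
        elif scheme == "descendant_descendant":
            ref = pair.reference
            n_match = len(ref)
            same = pair.s1[ref[:, 0]] == pair.s2[ref[:, 1]]
            len1 = pair.core1[1] - pair.core1[0]
            len2 = pair.core2[1] - pair.core2[0]
            gaps = (len1 - n_match) + (len2 - n_match)
            ids.append(same.mean() if n_match else 0.0)
            indels.append(gaps / (n_match + gaps))
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
    return 100.0 * float(np.mean(ids)), 100.0 * float(np.mean(indels))
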