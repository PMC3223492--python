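"""Amino-acid mutation model and substitution scoring matrices.

The generative engine is the classic Dayhoff point-accepted-mutation (PAM)
model: a 20-state Markov chain whose one-step transition matrix (``PAM1``)
produces on average one accepted substitution per 100 residues per step.
The chain is reversible with respect to the Dayhoff equilibrium amino-acid
frequencies, so sequences drawn from those frequencies stay stationary in
composition while diverging in identity.

``PAM1`` is built from the embedded Dayhoff (1978) exchangeabilities ``s_ij``
and frequencies ``pi_j`` as ``expm(t*Q)`` with ``Q_ij = s_ij * pi_j``
(diagonal set so rows sum to zero) and ``t`` calibrated so that the expected
fraction of sites that change in one step is exactly 1%.

Scoring matrices (log-odds weights for alignment) are kept on the
conventional ``10*log10`` scale: ``PAM250`` here is the original Dayhoff
one-decimal matrix (it rounds to the familiar NCBI integer PAM250), and
``Gonnet250`` is the Gonnet-Cohen-Benner 1992 matrix at its native scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import IO

import numpy as np
from Bio.Align import substitution_matrices
from scipy.linalg import expm
from scipy.optimize import brentq

#: Conventional one-letter amino-acid alphabet (Dayhoff/NCBI row order).
ALPHABET = "ARNDCQEGHILKMFPSTWYV"
N_AA = len(ALPHABET)

_CODE = {a: i for i, a in enumerate(ALPHABET)}


def encode(seq: str) -> np.ndarray:
    """Encode a residue string as uint8 indices into :data:`ALPHABET`."""
    try:
        return np.fromiter((_CODE[c] for c in seq), dtype=np.uint8, count=len(seq))
    except KeyError as exc:  # pragma: no cover - trivial re-raise
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


@dataclass(frozen=True)
class MutationModel:
    """One-PAM Markov mutation model over the 20 amino acids.

    Attributes
    ----------
    alphabet : str
        Residue order of the matrix rows/columns.
    pam1 : (20, 20) ndarray
        Per-site transition probabilities for one PAM step
        (row = current residue, column = next residue).
    background : (20,) ndarray
        Equilibrium amino-acid frequencies; also the composition of
        newly generated random sequence.
    """

    alphabet: str
    pam1: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        if self.pam1.shape != (N_AA, N_AA):
            raise ValueError("pam1 must be 20x20")
        if not np.allclose(self.pam1.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("pam1 rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if np.any(self.background <= 0):
            raise ValueError("background entries must be positive")


@dataclass(frozen=True)
class ScoringMatrix:
    """Symmetric 20x20 residue-substitution weights (log-odds units)."""

    name: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.scores.shape != (N_AA, N_AA):
            raise ValueError("scores must be 20x20")
        if not np.allclose(self.scores, self.scores.T, atol=1e-9):
            raise ValueError(f"{self.name}: scores must be symmetric")

    def pair_score(self, a: str, b: str) -> float:
        return float(self.scores[_CODE[a], _CODE[b]])


def _data_path(name: str) -> Path:
    return Path(str(resources.files("alnbench").joinpath("data", name)))


def _load_dayhoff_data() -> tuple[np.ndarray, np.ndarray]:
    exch = np.zeros((N_AA, N_AA))
    with open(_data_path("dayhoff_exchangeabilities.txt")) as fh:
        row = 1
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            assert parts[0] == ALPHABET[row]
            vals = [float(x) for x in parts[1:]]
            exch[row, :row] = vals
            exch[:row, row] = vals
            row += 1
    freqs = np.zeros(N_AA)
    with open(_data_path("dayhoff_frequencies.tsv")) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            aa, val = line.split()
            freqs[_CODE[aa]] = float(val)
    return exch, freqs / freqs.sum()


@lru_cache(maxsize=1)
def dayhoff_model() -> MutationModel:
    """The Dayhoff PAM mutation model (PAM1 calibrated to 1% change/step)."""
    exch, pi = _load_dayhoff_data()
    q = exch * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))

    def mean_change(t: float) -> float:
        return 1.0 - pi @ np.diag(expm(q * t))

    t1 = brentq(lambda t: mean_change(t) - 0.01, 1e-8, 1.0, xtol=1e-14)
    pam1 = expm(q * t1)
    # expm leaves ~1e-16 row-sum error; renormalize so powers stay stochastic
    pam1 /= pam1.sum(axis=1, keepdims=True)
    return MutationModel(alphabet=ALPHABET, pam1=pam1, background=pi)


def pam_power(model: MutationModel, n: int) -> np.ndarray:
    """``pam1`` raised to the ``n``-th power (n-step transition matrix)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return np.linalg.matrix_power(model.pam1, n)


def expected_identity(model: MutationModel, n: int, scheme: str) -> float:
    """Expected fraction of identical sites after ``n`` PAM steps.

    ``ancestor_descendant`` compares a stationary ancestor with its n-step
    descendant; ``descendant_descendant`` compares two descendants evolved
    independently for ``n`` steps each from the same ancestor (for a
    reversible chain this equals the ancestor-descendant identity at 2n).
    """
    mn = pam_power(model, n)
    pi = model.background
    if scheme == "ancestor_descendant":
        return float(pi @ np.diag(mn))
    if scheme == "descendant_descendant":
        return float(pi @ (mn * mn).sum(axis=1))
    raise ValueError(f"unknown scheme {scheme!r}")


def mean_random_score(matrix: ScoringMatrix, background: np.ndarray) -> float:
    """Expected substitution weight of two independent background residues.

    This is the per-column score baseline ``sum_ij p_i p_j S_ij`` of a
    gapless alignment of unrelated sequences; it is negative for any
    sensible log-odds matrix.
    """
    background = np.asarray(background, dtype=float)
    if background.shape != (N_AA,):
        raise ValueError("background must have length 20")
    if not np.isclose(background.sum(), 1.0, atol=1e-6):
        raise ValueError("background must sum to 1")
    return float(background @ matrix.scores @ background)


def make_log_odds(model: MutationModel, n: int, scale: float = 10.0,
                  round_scores: bool = False) -> ScoringMatrix:
    """Derive the PAM-``n`` log-odds scoring matrix from the mutation model.

    ``S_ij = scale * log10((pam1^n)_ij / background_j)``, symmetrized by
    averaging with its transpose (exact under reversibility up to numerics).
    ``scale=10`` with ``round_scores=True`` reproduces the familiar integer
    PAM matrices to within one unit.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if np.any(model.background <= 0):
        raise ValueError("background entries must be positive")
    mn = pam_power(model, n)
    with np.errstate(divide="raise"):
        s = scale * np.log10(mn / model.background[None, :])
    s = (s + s.T) / 2.0
    if round_scores:
        s = np.round(s)
    return ScoringMatrix(name=f"PAM{n}", scores=s)


def _from_biopython(name: str, scale: float, label: str) -> ScoringMatrix:
    mat = substitution_matrices.load(name)
    s = np.array([[mat[a, b] for b in ALPHABET] for a in ALPHABET], dtype=float)
    return ScoringMatrix(name=label, scores=s * scale)


@lru_cache(maxsize=None)
def load_matrix(name: str) -> ScoringMatrix:
    """Load a named scoring matrix.

    ``PAM250``   -- Dayhoff 1978 250-PAM log-odds, 10*log10 scale with
                    one-decimal entries (rounds to the NCBI integer PAM250).
    ``Gonnet250`` -- Gonnet-Cohen-Benner 1992 matrix, native 10*log10 scale.
    ``PAM<n>``   -- derived from the mutation model via :func:`make_log_odds`.
    """
    if name == "PAM250":
        return _from_biopython("DAYHOFF", 10.0, "PAM250")
    if name.lower() in ("gonnet250", "gonnet1992"):
        return _from_biopython("GONNET1992", 1.0, "Gonnet250")
    if name.upper().startswith("PAM") and name[3:].isdigit():
        return make_log_odds(dayhoff_model(), int(name[3:]))
    raise ValueError(f"unknown matrix {name!r}")


def write_matrix(matrix: ScoringMatrix, fh: IO[str]) -> None:
    """Write in NCBI-style square text format (header row + labelled rows)."""
    fh.write("# " + matrix.name + "\n")
    fh.write("   " + "  ".join(ALPHABET) + "\n")
    for i, aa in enumerate(ALPHABET):
        row = " ".join(f"{matrix.scores[i, j]:g}" for j in range(N_AA))
        fh.write(f"{aa} {row}\n")


def read_matrix(fh: IO[str], name: str = "custom") -> ScoringMatrix:
    """Read an NCBI-style square matrix, re-indexing rows/columns to
    the conventional alphabet order."""
    header: list[str] | None = None
    rows: dict[str, list[float]] = {}
    for line in fh:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if header is None:
            header = parts
            continue
        rows[parts[0]] = [float(x) for x in parts[1:]]
    if header is None or set(header) < set(ALPHABET) or set(rows) < set(ALPHABET):
        raise ValueError("matrix file must cover all 20 standard residues")
    col = {a: j for j, a in enumerate(header)}
    s = np.array([[rows[a][col[b]] for b in ALPHABET] for a in ALPHABET])
    return ScoringMatrix(name=name, scores=s)
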