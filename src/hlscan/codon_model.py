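"""Goldman-Yang (GY94-style) codon substitution machinery.

The instantaneous rate between two sense codons differing at exactly one
nucleotide position is proportional to the target codon's equilibrium
frequency, multiplied by kappa for transitions and by omega for
nonsynonymous changes; all multi-nucleotide changes are instantaneous-rate
zero.  The matrix is rescaled so the expected substitution rate at
equilibrium is one, making branch lengths expected substitutions per codon.

Transition probabilities exp(Qt) are computed through the symmetric
eigendecomposition of Pi^1/2 Q Pi^-1/2 (valid because the chain is
reversible); one decomposition serves every branch length on the tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .alignment import CodonAlignment
from .genetics import is_transition, standard_code

#: Default pseudocount for empirical codon frequencies; keeps Q irreducible
#: when short genes have unobserved codons.
DEFAULT_PSEUDOCOUNT = 1e-6


@dataclass(frozen=True)
class CodonFrequencies:
    """Equilibrium frequencies over the 61 sense codons (F61-style)."""

    pi: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        if pi.shape != (61,):
            raise ValueError("pi must be a 61-vector")
        if np.any(pi <= 0):
            raise ValueError("all codon frequencies must be > 0")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("codon frequencies must sum to 1")

    @classmethod
    def uniform(cls) -> "CodonFrequencies":
        return cls(np.full(61, 1.0 / 61.0))


def estimate_codon_frequencies(
    alignment: CodonAlignment, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> CodonFrequencies:
    """Empirical codon-table frequencies (codeml CodonFreq=3 analogue).

    Counts every unambiguous sense codon across all taxa and sites, adds
    ``pseudocount`` to each of the 61 cells, and normalizes.
    """
    flat = alignment.sites.ravel()
    observed = flat[flat >= 0]
    if observed.size == 0 and pseudocount <= 0:
        raise ValueError("alignment contains no countable codons")
    counts = np.bincount(observed, minlength=61).astype(float) + pseudocount
    if np.any(counts <= 0):
        raise ValueError(
            "zero-frequency codons present; use a positive pseudocount"
        )
    return CodonFrequencies(counts / counts.sum())


@lru_cache(maxsize=1)
def _pair_structure() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean 61x61 masks (single-difference, transition, nonsynonymous)
    over ordered sense-codon pairs; multi-difference pairs are False in
    the single-difference mask and get rate zero."""
    code = standard_code()
    n = code.n_states
    single = np.zeros((n, n), dtype=bool)
    transition = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(code.sense_codons):
        for j, cj in enumerate(code.sense_codons):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            a, b = diffs[0]
            transition[i, j] = is_transition(a, b)
            nonsyn[i, j] = code.amino_acid(ci) != code.amino_acid(cj)
    return single, transition, nonsyn


@dataclass
class CodonRateMatrix:
    """Scaled GY94 rate matrix with its reversible eigendecomposition."""

    kappa: float
    omega: float
    pi: CodonFrequencies
    Q: np.ndarray = field(init=False)
    #: mean substitution rate of the unscaled matrix at equilibrium;
    #: dividing by it is what normalizes Q to mean rate 1
    mean_rate: float = field(init=False)
    _eigvals: np.ndarray = field(init=False, repr=False)
    _left: np.ndarray = field(init=False, repr=False)
    _right: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        single, transition, nonsyn = _pair_structure()
        pi = self.pi.pi
        rates = np.where(single, pi[None, :], 0.0)
        rates = rates * np.where(transition, self.kappa, 1.0)
        rates = rates * np.where(nonsyn, self.omega, 1.0)
        np.fill_diagonal(rates, 0.0)
        np.fill_diagonal(rates, -rates.sum(axis=1))
        scale = -np.dot(pi, np.diag(rates))
        if scale <= 0:
            raise ValueError("degenerate rate matrix (zero mean rate)")
        self.mean_rate = float(scale)
        self.Q = rates / scale
        # Pi^1/2 Q Pi^-1/2 is symmetric for a reversible chain.
        sq = np.sqrt(pi)
        sym = (sq[:, None] * self.Q) / sq[None, :]
        sym = 0.5 * (sym + sym.T)  # kill round-off asymmetry
        eigvals, vecs = np.linalg.eigh(sym)
        self._eigvals = eigvals
        self._right = vecs / sq[:, None]      # rows scaled: Pi^-1/2 U
        self._left = vecs * sq[:, None]       # Pi^1/2 U

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt), rows summing to 1; entries clamped to [0, 1]."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        w = np.exp(self._eigvals * t)
        P = (self._right * w[None, :]) @ self._left.T
        np.clip(P, 0.0, 1.0, out=P)
        return P

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Batched P(t) for a vector of branch lengths, shape (B, 61, 61)."""
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ValueError("branch lengths must be >= 0")
        w = np.exp(np.outer(ts, self._eigvals))  # (B, 61)
        P = (self._right[None, :, :] * w[:, None, :]) @ self._left.T
        np.clip(P, 0.0, 1.0, out=P)
        return P

    def dP_dt(self, t: float) -> np.ndarray:
        """Derivative of P(t) with respect to branch length."""
        w = self._eigvals * np.exp(self._eigvals * t)
        return (self._right * w[None, :]) @ self._left.T


def gy94_mean_rate(kappa: float, omega: float, pi: CodonFrequencies) -> float:
    """Equilibrium mean rate of the *unscaled* GY94 matrix.

    Cheap closed form used for mixture-model rate normalization:
    mu = S_tv + kappa*S_ts + omega*(N_tv + kappa*N_ts) with S/N the
    pi-weighted sums over synonymous/nonsynonymous single-difference pairs.
    """
    single, transition, nonsyn = _pair_structure()
    pp = np.outer(pi.pi, pi.pi)
    s_ts = pp[single & transition & ~nonsyn].sum()
    s_tv = pp[single & ~transition & ~nonsyn].sum()
    n_ts = pp[single & transition & nonsyn].sum()
    n_tv = pp[single & ~transition & nonsyn].sum()
    return float(s_tv + kappa * s_ts + omega * (n_tv + kappa * n_ts))


def build_rate_matrix(kappa: float, omega: float,
                      pi: CodonFrequencies) -> CodonRateMatrix:
    """Construct the scaled GY94 rate matrix for (kappa, omega, pi)."""
    return CodonRateMatrix(kappa=kappa, omega=omega, pi=pi)


def transition_matrix(Q: CodonRateMatrix, t: float) -> np.ndarray:
    """Functional wrapper around :meth:`CodonRateMatrix.transition_matrix`."""
    return Q.transition_matrix(t)
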