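"""Codon substitution rate matrices and transition probabilities.

Implements the Goldman–Yang style parameterization used by branch-site
models: instantaneous rate ``q_ij`` between codons differing at a single
nucleotide position is proportional to the target codon's equilibrium
frequency, multiplied by kappa for transitions and by omega for
nonsynonymous changes.  Matrices are scaled so one unit of branch length
equals one expected substitution per codon at equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetic_code import IS_NONSYNONYMOUS, IS_TRANSITION, N_CODONS, SINGLE_DIFF

__all__ = ["CodonSubstModel", "build_q_matrix", "transition_matrix", "uniform_codon_freqs"]


def uniform_codon_freqs() -> np.ndarray:
    """Uniform equilibrium frequencies over the 61 sense codons."""
    return np.full(N_CODONS, 1.0 / N_CODONS)


@dataclass(frozen=True)
class CodonSubstModel:
    """A reversible 61-state codon substitution model.

    Attributes
    ----------
    kappa : transition/transversion rate ratio (> 0).
    omega : nonsynonymous/synonymous rate ratio (>= 0).
    codon_freqs : equilibrium frequencies pi over the 61 sense codons.
    Q : rate matrix, rows summing to zero, scaled so that
        ``-sum_i pi_i Q_ii = 1``.
    prescale_rate : the expected substitution rate of the unscaled
        matrix (kappa/omega multipliers times target frequencies);
        mixture models use it to express branch lengths as expected
        substitutions averaged over site classes.
    """

    kappa: float
    omega: float
    codon_freqs: np.ndarray
    Q: np.ndarray
    prescale_rate: float = 1.0
    # Symmetric-similarity eigendecomposition, cached for fast exp(Qt):
    # Q = D^{-1/2} (V L V^T) D^{1/2} with D = diag(pi).
    _eigvals: np.ndarray = field(repr=False, default=None)
    _eigvecs: np.ndarray = field(repr=False, default=None)
    _sqrt_pi: np.ndarray = field(repr=False, default=None)


def build_q_matrix(kappa: float, omega: float, codon_freqs: np.ndarray) -> CodonSubstModel:
    """Construct the scaled codon rate matrix.

    Raises
    ------
    ValueError
        If kappa <= 0, omega < 0, or the frequency vector is not a valid
        distribution over the 61 sense codons (sum within 1e-8 of 1).
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    if omega < 0:
        raise ValueError(f"omega must be nonnegative, got {omega}")
    pi = np.asarray(codon_freqs, dtype=float)
    if pi.shape != (N_CODONS,):
        raise ValueError(f"codon_freqs must have length {N_CODONS}, got {pi.shape}")
    if np.any(pi < 0):
        raise ValueError("codon_freqs must be nonnegative")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError(f"codon_freqs must sum to 1 (got {pi.sum():.10f})")

    mult = np.where(SINGLE_DIFF, 1.0, 0.0)
    mult = np.where(SINGLE_DIFF & IS_TRANSITION, kappa, mult)
    mult = np.where(SINGLE_DIFF & IS_NONSYNONYMOUS, mult * omega, mult)
    Q = mult * pi[np.newaxis, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))

    # Scale to one expected substitution per codon per unit time.
    rate = float(-np.dot(pi, np.diag(Q)))
    if rate > 0:
        Q = Q / rate

    # pi_i q_ij = pi_j q_ji, so S = D^{1/2} Q D^{-1/2} is symmetric when
    # pi > 0; guard zero frequencies for the decomposition.
    safe_pi = np.where(pi > 0, pi, 1e-300)
    sqrt_pi = np.sqrt(safe_pi)
    S = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
    eigvals, eigvecs = np.linalg.eigh((S + S.T) / 2.0)

    return CodonSubstModel(
        kappa=kappa,
        omega=omega,
        codon_freqs=pi,
        Q=Q,
        prescale_rate=rate,
        _eigvals=eigvals,
        _eigvecs=eigvecs,
        _sqrt_pi=sqrt_pi,
    )


def transition_matrix(model: CodonSubstModel, t: float) -> np.ndarray:
    """Transition probability matrix P(t) = exp(Qt) for branch length t >= 0."""
    if t < 0:
        raise ValueError(f"branch length must be nonnegative, got {t}")
    V = model._eigvecs
    inner = (V * np.exp(model._eigvals * t)) @ V.T
    P = inner / model._sqrt_pi[:, None] * model._sqrt_pi[None, :]
    np.clip(P, 0.0, None, out=P)
    # renormalize away rounding error so rows are exactly stochastic
    P /= P.sum(axis=1, keepdims=True)
    return P
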