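"""Independent oracles used by the test suite.

Everything here is deliberately written from scratch — its own codon
tables (via Biopython translation), its own rate matrix assembly, and
matrix exponentials from scipy — so that agreement with the package is
a genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Seq import Seq
from scipy.linalg import expm

NUCS = "TCAG"
CODONS = [
    "".join(c)
    for c in itertools.product(NUCS, repeat=3)
    if str(Seq("".join(c)).translate()) != "*"
]
AA = {c: str(Seq(c).translate()) for c in CODONS}


def naive_q(kappa: float, omega: float, pi: np.ndarray) -> tuple[np.ndarray, float]:
    """Unnormalized-rate codon Q built by direct enumeration.

    Returns the matrix scaled to one expected substitution per unit
    time and the pre-scaling expected rate.
    """
    n = len(CODONS)
    Q = np.zeros((n, n))
    purines = set("AG")
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(x, y) for x, y in zip(ci, cj) if x != y]
            if len(diffs) != 1:
                continue
            x, y = diffs[0]
            rate = pi[j]
            if (x in purines) == (y in purines):
                rate *= kappa
            if AA[ci] != AA[cj]:
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = float(-np.dot(pi, np.diag(Q)))
    return Q / mean_rate, mean_rate


def star_tree_mixture_loglik(
    states: np.ndarray,
    lengths: np.ndarray,
    is_fg: np.ndarray,
    classes: list[tuple[float, float, float]],
    kappa: float,
    pi: np.ndarray,
) -> float:
    """Exhaustive-enumeration log-likelihood on a star tree.

    ``states`` is (n_leaves, n_sites) with -1 for ambiguous codons;
    ``classes`` lists (proportion, omega_bg, omega_fg).  Branch lengths
    are expected substitutions averaged over the class mixture, matched
    independently of the package's implementation.
    """
    qs = {}
    for _, wb, wf in classes:
        for w in (wb, wf):
            if w not in qs:
                qs[w] = naive_q(kappa, w, pi)
    r_bg = sum(p * qs[wb][1] for p, wb, _ in classes)
    r_fg = sum(p * qs[wf][1] for p, _, wf in classes)

    n_leaves, n_sites = states.shape
    site_lik = np.zeros(n_sites)
    for prop, wb, wf in classes:
        if prop == 0:
            continue
        Ps = []
        for leaf in range(n_leaves):
            w = wf if is_fg[leaf] else wb
            Q, rho = qs[w]
            scale = r_fg if is_fg[leaf] else r_bg
            Ps.append(expm(Q * lengths[leaf] * rho / scale))
        for s in range(n_sites):
            total = 0.0
            for root in range(len(CODONS)):
                term = pi[root]
                for leaf in range(n_leaves):
                    st = states[leaf, s]
                    term *= 1.0 if st < 0 else Ps[leaf][root, st]
                total += term
            site_lik[s] += prop * total
    return float(np.log(site_lik).sum())


def stepup_bh_reference(p: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini–Hochberg rejections by the textbook step-up rule."""
    m = len(p)
    order = np.argsort(p)
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= alpha * i / m:
            k = i
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k]] = True
    return rejected
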