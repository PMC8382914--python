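"""Mixture-aware p-value machinery.

Branch-site LRT p-value cohorts are not uniform under the null: a large
fraction sits exactly at 1 (zero statistics from the boundary
condition, further inflated by conserved genes that misspecify the
null).  This module provides the diagnostics and corrections built
around that structure: the point-mass proportion, halving/scaling
adjustments, Benjamini–Hochberg FDR, and the robust FDR estimator of
Pounds & Cheng applied to a truncated p-value pool (p < 0.98) so the
artifactual right-tail mass never enters the correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AdjustmentConfig",
    "mass_at_one",
    "adjust",
    "bh_fdr",
    "robust_fdr",
    "adjustment_table",
]

ADJUST_MODES = ("halve", "scale_by_nonzero_fraction", "none")


@dataclass(frozen=True)
class AdjustmentConfig:
    """Knobs for the p-value corrections.

    alpha : FDR level.
    truncation_cutoff : ceiling defining the robust-FDR pool (entries
        at or above it are excluded as misspecification artifacts).
    zero_tolerance : how close to 1 a p-value must be to count toward
        the point mass at 1.
    pi0_factor : multiplier on the mean p-value in the robust null-
        proportion estimate ``pi0 = min(1, pi0_factor * mean(p))``.
    """

    alpha: float = 0.05
    truncation_cutoff: float = 0.98
    zero_tolerance: float = 1e-12
    pi0_factor: float = 2.0

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.truncation_cutoff <= 1):
            raise ValueError("truncation_cutoff must lie in (0, 1]")


def _validate(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def mass_at_one(pvalues, tolerance: float = 1e-12) -> float:
    """Fraction of p-values within ``tolerance`` of 1."""
    p = _validate(pvalues)
    return float(np.mean(p >= 1.0 - tolerance))


def adjust(pvalues, mode: str) -> np.ndarray:
    """Elementwise boundary-condition adjustment.

    ``halve`` divides every p by two (the standard correction for the
    50:50 chi-square/point-mass mixture); ``scale_by_nonzero_fraction``
    multiplies by the observed fraction of p-values below 1 (the
    empirical share of nonzero statistics); ``none`` passes through.
    All modes are monotone, so rankings are preserved.
    """
    p = _validate(pvalues)
    if mode == "halve":
        return p / 2.0
    if mode == "scale_by_nonzero_fraction":
        return p * float(np.mean(p < 1.0))
    if mode == "none":
        return p.copy()
    raise ValueError(f"mode must be one of {ADJUST_MODES}, got {mode!r}")


def bh_fdr(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up procedure.

    Returns (rejection flags, monotone adjusted p-values) in the input
    order.
    """
    p = _validate(pvalues)
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    rejected, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return rejected, q


def robust_fdr(
    pvalues,
    cutoff: float = 0.98,
    config: AdjustmentConfig | None = None,
) -> pd.DataFrame:
    """Robust FDR estimates on the pool of p-values below ``cutoff``.

    Implements the one-sided-robust estimator of Pounds & Cheng (2006):
    the null proportion is estimated as ``pi0 = min(1, 2 * mean(p))``
    over the pool, each pooled p-value receives
    ``q_(i) = pi0 * m * p_(i) / i`` and the estimates are monotonized
    from the largest p downward.  Entries at or above the cutoff are
    flagged ``excluded`` with no estimate — the operational rule that
    keeps the artifactual mass near 1 out of the correction.

    Returns a DataFrame aligned with the input: ``p``, ``rfdr``,
    ``excluded``.
    """
    if config is not None:
        cutoff = config.truncation_cutoff
        pi0_factor = config.pi0_factor
    else:
        pi0_factor = 2.0
    p = _validate(pvalues)
    included = p < cutoff
    if not included.any():
        raise ValueError(f"no p-values below the cutoff {cutoff}")
    pool = p[included]
    m = pool.size
    pi0 = min(1.0, pi0_factor * float(pool.mean()))
    order = np.argsort(pool, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, pi0 * m * pool[order] / ranks)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    rfdr = np.full(p.size, np.nan)
    rfdr[included] = q
    return pd.DataFrame({"p": p, "rfdr": rfdr, "excluded": ~included})


def adjustment_table(
    gene_ids,
    branches,
    pvalues,
    config: AdjustmentConfig | None = None,
) -> pd.DataFrame:
    """All corrections side by side for a pooled p-value cohort.

    Columns: gene_id, branch, p_raw, p_halved, p_scaled, bh_q, rfdr,
    excluded_flag (True where the robust-FDR pool excluded the entry).
    """
    config = config or AdjustmentConfig()
    p = _validate(pvalues)
    if not (len(gene_ids) == len(branches) == p.size):
        raise ValueError("gene_ids, branches and pvalues must align")
    _, bh_q = bh_fdr(p, config.alpha)
    rf = robust_fdr(p, config=config)
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "branch": list(branches),
            "p_raw": p,
            "p_halved": adjust(p, "halve"),
            "p_scaled": adjust(p, "scale_by_nonzero_fraction"),
            "bh_q": bh_q,
            "rfdr": rf["rfdr"].to_numpy(),
            "excluded_flag": rf["excluded"].to_numpy(),
        }
    )
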