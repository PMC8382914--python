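"""Empirical-Bayes site-class posteriors for a fitted Model A.

Given the alternative-model MLEs, each codon site's posterior
probability of belonging to classes {0, 1, 2a, 2b} follows from Bayes'
rule on the per-class site likelihoods weighted by the fitted class
proportions (naive empirical Bayes at the MLEs; externally computed BEB
tables can be fed to the downstream filters instead).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .alignment import CodonAlignment
from .fit import ModelAFit
from .likelihood import LikelihoodEngine, ModelASpec
from .trees import LabeledTree

__all__ = ["site_class_posteriors", "CLASS_LABELS"]

CLASS_LABELS = ("0", "1", "2a", "2b")


def site_class_posteriors(
    fit_alt: ModelAFit,
    aln: CodonAlignment,
    ltree: LabeledTree,
) -> pd.DataFrame:
    """Per-site posterior class membership at the alternative MLEs.

    Returns a DataFrame with 1-based amino-acid ``position`` and columns
    ``p_class0``, ``p_class1``, ``p_class2a``, ``p_class2b`` summing to
    one per site.  Raises if the fit did not converge.
    """
    if not fit_alt.converged:
        raise ValueError("cannot compute posteriors from an unconverged fit")
    engine = LikelihoodEngine(aln, ltree)
    props, loglik = engine.class_site_log_likelihoods(
        ModelASpec(fit_alt.params), fit_alt.branch_lengths
    )
    with np.errstate(divide="ignore"):
        logw = np.where(props > 0, np.log(np.where(props > 0, props, 1.0)), -np.inf)
    joint = loglik + logw[:, None]
    joint -= joint.max(axis=0, keepdims=True)
    post = np.exp(joint)
    post /= post.sum(axis=0, keepdims=True)
    per_site = post[:, engine.patterns.site_to_pattern]
    return pd.DataFrame(
        {
            "position": np.arange(1, aln.n_codons + 1),
            "p_class0": per_site[0],
            "p_class1": per_site[1],
            "p_class2a": per_site[2],
            "p_class2b": per_site[3],
        }
    )
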