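"""Universal genetic code tables for the 61-state sense-codon alphabet.

The codon substitution models in this package operate on the 61 sense
codons of the universal (standard) genetic code; the three stop codons
(TAA, TAG, TGA) are never valid observed states.  This module builds,
once at import time, the index maps and pairwise classification arrays
(single-nucleotide difference, transition vs. transversion, synonymous
vs. nonsynonymous) that the rate-matrix construction needs.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

NUCLEOTIDES = "TCAG"
_TABLE = unambiguous_dna_by_id[1]  # the standard code

STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))

#: The 61 sense codons in TCAG order (codeml's canonical ordering).
SENSE_CODONS: tuple[str, ...] = tuple(
    "".join(c)
    for c in itertools.product(NUCLEOTIDES, repeat=3)
    if "".join(c) not in _TABLE.stop_codons
)

N_CODONS = len(SENSE_CODONS)  # 61

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: Amino acid encoded by each sense codon, aligned with SENSE_CODONS.
AMINO_ACIDS: tuple[str, ...] = tuple(_TABLE.forward_table[c] for c in SENSE_CODONS)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a<->b is a transition."""
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def _build_pair_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    nonsyn = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            a, b = diffs[0]
            transition[i, j] = is_transition(a, b)
            nonsyn[i, j] = AMINO_ACIDS[i] != AMINO_ACIDS[j]
    return single, transition, nonsyn


#: Boolean 61x61 tables over ordered codon pairs (i, j), i != j:
#: SINGLE_DIFF  -- codons differ at exactly one position;
#: IS_TRANSITION -- that difference is a transition (only meaningful
#:                  where SINGLE_DIFF);
#: IS_NONSYNONYMOUS -- the two codons encode different amino acids.
SINGLE_DIFF, IS_TRANSITION, IS_NONSYNONYMOUS = _build_pair_tables()

#: Sentinel state index for a gap or missing codon (fully ambiguous).
AMBIGUOUS_STATE = -1

GAP_CODON = "---"


def encode_codon(codon: str) -> int:
    """Map a codon string to its state index.

    Gaps (``---``), codons containing ``N``/``?``/``-`` and other
    unresolvable triplets map to :data:`AMBIGUOUS_STATE`.  An in-frame
    stop codon raises ``ValueError``: observed stops are an input error
    (they are filtered out of coding alignments upstream).
    """
    codon = codon.upper()
    if codon in CODON_INDEX:
        return CODON_INDEX[codon]
    if codon in STOP_CODONS:
        raise ValueError(f"in-frame stop codon {codon!r} is not a valid state")
    if any(ch not in "ACGT" for ch in codon):
        return AMBIGUOUS_STATE
    raise ValueError(f"unrecognized codon {codon!r}")
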