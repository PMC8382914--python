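"""In-frame codon alignments: container, FASTA I/O, and F3x4 frequencies.

A :class:`CodonAlignment` is the per-gene unit of analysis: one in-frame
codon sequence per taxon, all the same length, with gaps (``---``) and
missing/ambiguous codons treated as fully ambiguous states during
likelihood computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import (
    AMBIGUOUS_STATE,
    N_CODONS,
    NUCLEOTIDES,
    SENSE_CODONS,
    encode_codon,
)

__all__ = ["CodonAlignment", "read_codon_fasta", "write_codon_fasta", "estimate_f3x4"]


@dataclass(frozen=True)
class CodonAlignment:
    """An aligned set of in-frame codon sequences.

    Attributes
    ----------
    taxon_ids : unique sequence names, in input order.
    states : int array of shape (n_taxa, n_codons); each entry is a
        sense-codon index in [0, 61) or -1 for a gap/missing codon.
    """

    taxon_ids: tuple[str, ...]
    states: np.ndarray

    def __post_init__(self):
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("taxon_ids must be unique")
        if self.states.ndim != 2 or self.states.shape[0] != len(self.taxon_ids):
            raise ValueError("states must be (n_taxa, n_codons)")
        if self.states.shape[1] < 1:
            raise ValueError("alignment must contain at least one codon column")
        if self.states.max(initial=-1) >= N_CODONS or self.states.min(initial=0) < -1:
            raise ValueError("invalid codon state index")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_codons(self) -> int:
        return self.states.shape[1]

    @classmethod
    def from_sequences(cls, taxon_ids, sequences) -> "CodonAlignment":
        """Build from nucleotide strings (lengths must be equal multiples of 3)."""
        taxon_ids = tuple(taxon_ids)
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise ValueError("all sequences must have the same length")
        (length,) = lengths
        if length % 3 != 0 or length == 0:
            raise ValueError(f"sequence length {length} is not a positive multiple of 3")
        states = np.empty((len(taxon_ids), length // 3), dtype=np.int64)
        for row, seq in enumerate(sequences):
            seq = str(seq).upper().replace("?", "N")
            for col in range(length // 3):
                states[row, col] = encode_codon(seq[3 * col : 3 * col + 3])
        return cls(taxon_ids=taxon_ids, states=states)

    def sequence_strings(self) -> list[str]:
        """Decode back to nucleotide strings (ambiguous codons as NNN)."""
        out = []
        for row in self.states:
            out.append(
                "".join(SENSE_CODONS[s] if s >= 0 else "NNN" for s in row)
            )
        return out

    def subset_taxa(self, keep) -> "CodonAlignment":
        keep = list(keep)
        idx = [self.taxon_ids.index(t) for t in keep]
        return CodonAlignment(taxon_ids=tuple(keep), states=self.states[idx])

    def subset_sites(self, columns) -> "CodonAlignment":
        return CodonAlignment(taxon_ids=self.taxon_ids, states=self.states[:, list(columns)])


def read_codon_fasta(path) -> CodonAlignment:
    """Read an aligned in-frame FASTA file into a CodonAlignment.

    Gap codons are ``---``; codons containing ``N`` or ``?`` are missing.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return CodonAlignment.from_sequences(
        [r.id for r in records], [str(r.seq) for r in records]
    )


def write_codon_fasta(aln: CodonAlignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=tid, description="")
        for tid, seq in zip(aln.taxon_ids, aln.sequence_strings())
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, str(path), "fasta")


def estimate_f3x4(aln: CodonAlignment) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide counts.

    Nucleotide frequencies are tallied separately at each of the three
    codon positions over all non-missing codons; each sense codon's
    frequency is the product of its three positional frequencies,
    renormalized over the 61 sense codons (the standard codeml default).
    """
    observed = aln.states[aln.states >= 0]
    if observed.size == 0:
        raise ValueError("alignment contains no non-missing codons")
    # counts[pos][nuc] over TCAG
    counts = np.zeros((3, 4))
    nuc_index = {n: i for i, n in enumerate(NUCLEOTIDES)}
    codon_nucs = np.array(
        [[nuc_index[c[pos]] for pos in range(3)] for c in SENSE_CODONS]
    )  # (61, 3)
    state_counts = np.bincount(observed, minlength=N_CODONS)
    for pos in range(3):
        for s, c in enumerate(state_counts):
            counts[pos, codon_nucs[s, pos]] += c
    pos_freqs = counts / counts.sum(axis=1, keepdims=True)
    freqs = (
        pos_freqs[0, codon_nucs[:, 0]]
        * pos_freqs[1, codon_nucs[:, 1]]
        * pos_freqs[2, codon_nucs[:, 2]]
    )
    total = freqs.sum()
    if total <= 0:
        raise ValueError("degenerate F3x4 frequencies")
    return freqs / total
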