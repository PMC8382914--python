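"""Orthology and alignment preprocessing rules.

Implements the upstream hygiene applied before any selection testing:
reciprocal-best-hit orthology from tabular BLAST results, selection of
one representative sequence per species, reference-anchored alignment
masking, taxon-count eligibility rules, and trimming of the reference
phylogeny to each gene's taxon set while preserving the foreground
bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import CodonAlignment
from .genetic_code import AMBIGUOUS_STATE
from .trees import ForegroundError, LabeledTree

__all__ = [
    "HitRecord",
    "EligibilityRule",
    "reciprocal_best_hits",
    "select_representative",
    "mask_alignment",
    "check_eligibility",
    "trim_tree",
]


@dataclass(frozen=True)
class HitRecord:
    query: str
    subject: str
    evalue: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("e-value must be nonnegative")


def _top_hits(hits) -> dict[str, HitRecord]:
    """Best hit per query (lowest e-value); ambiguous ties are an error."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query)
        if cur is None or h.evalue < cur.evalue:
            best[h.query] = h
        elif h.evalue == cur.evalue and h.subject != cur.subject:
            raise ValueError(
                f"query {h.query!r} has conflicting equal-scoring top hits "
                f"({cur.subject!r}, {h.subject!r})"
            )
    return best


def reciprocal_best_hits(
    forward_hits,
    reverse_hits,
    evalue_max: float = 1e-6,
) -> list[tuple[str, str]]:
    """Reciprocal-best-hit ortholog pairs.

    A pair (q, s) is kept only if s is q's top forward hit, q is s's
    top reverse hit, and both e-values pass the threshold (default
    1e-06).  Inputs are iterables of :class:`HitRecord` (or anything
    with query/subject/evalue attributes).
    """
    fwd = _top_hits(forward_hits)
    rev = _top_hits(reverse_hits)
    pairs = []
    for q, fh in sorted(fwd.items()):
        if fh.evalue > evalue_max:
            continue
        rh = rev.get(fh.subject)
        if rh is None or rh.subject != q or rh.evalue > evalue_max:
            continue
        pairs.append((q, fh.subject))
    return pairs


def select_representative(sequences: list[str], ids: list[str] | None = None):
    """The most complete sequence (fewest gap characters) per species.

    Ties break to the first sequence in input order.  Returns the
    winning sequence (and its id when ids are given).
    """
    if not sequences:
        raise ValueError("no sequences to choose from")
    gap_counts = [s.count("-") for s in sequences]
    idx = int(np.argmin(gap_counts))  # argmin takes the first minimum
    if ids is not None:
        return sequences[idx], ids[idx]
    return sequences[idx]


@dataclass(frozen=True)
class MaskReport:
    removed_columns: tuple[int, ...]  # 0-based codon columns gapped in reference
    removed_sequences: tuple[str, ...]
    masked_columns: tuple[int, ...]  # 0-based post-removal columns set to missing

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"action": "drop_column", "target": str(c), "rule": "gap in reference"}
            for c in self.removed_columns
        ]
        rows += [
            {"action": "drop_sequence", "target": t, "rule": "gap fraction > max"}
            for t in self.removed_sequences
        ]
        rows += [
            {"action": "mask_column", "target": str(c), "rule": "missing fraction > max"}
            for c in self.masked_columns
        ]
        return pd.DataFrame(rows, columns=["action", "target", "rule"])


def mask_alignment(
    aln: CodonAlignment,
    reference_id: str = "Homo_sapiens",
    seq_gap_max: float = 0.5,
    col_missing_max: float = 0.5,
) -> tuple[CodonAlignment, MaskReport]:
    """Reference-anchored masking in three ordered passes.

    1. Drop codon columns where the reference sequence has a gap or
       missing codon (insertions relative to the reference are not
       comparable).
    2. Drop sequences whose gap/missing fraction over the remaining
       columns exceeds ``seq_gap_max``.
    3. Convert columns whose missing fraction over the remaining taxa
       exceeds ``col_missing_max`` to fully missing.

    Returns the masked alignment and a removal log.  Raises if the
    reference is absent or the alignment would be emptied.
    """
    if reference_id not in aln.taxon_ids:
        raise ValueError(f"reference sequence {reference_id!r} absent from alignment")
    ref_row = aln.taxon_ids.index(reference_id)

    ref_gap = aln.states[ref_row] == AMBIGUOUS_STATE
    removed_cols = tuple(int(c) for c in np.where(ref_gap)[0])
    keep_cols = np.where(~ref_gap)[0]
    if keep_cols.size == 0:
        raise ValueError("masking removed every column (reference all-gap)")
    states = aln.states[:, keep_cols]

    gap_frac = (states == AMBIGUOUS_STATE).mean(axis=1)
    drop_seq = gap_frac > seq_gap_max
    removed_seqs = tuple(t for t, d in zip(aln.taxon_ids, drop_seq) if d)
    keep_taxa = [t for t, d in zip(aln.taxon_ids, drop_seq) if not d]
    if not keep_taxa:
        raise ValueError("masking removed every sequence")
    states = states[~drop_seq]

    missing_frac = (states == AMBIGUOUS_STATE).mean(axis=0)
    mask_cols = np.where(missing_frac > col_missing_max)[0]
    states = states.copy()
    states[:, mask_cols] = AMBIGUOUS_STATE

    masked = CodonAlignment(taxon_ids=tuple(keep_taxa), states=states)
    report = MaskReport(
        removed_columns=removed_cols,
        removed_sequences=removed_seqs,
        masked_columns=tuple(int(c) for c in mask_cols),
    )
    return masked, report


@dataclass(frozen=True)
class EligibilityRule:
    """Taxon-representation requirements for running a branch test."""

    min_total_taxa: int = 10
    min_descendants_per_focal_clade: int = 2
    single_taxon_exempt_branches: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.min_total_taxa < 1 or self.min_descendants_per_focal_clade < 1:
            raise ValueError("thresholds must be >= 1")


def check_eligibility(
    taxa,
    clade_definitions: dict[str, set[str]],
    rule: EligibilityRule = EligibilityRule(),
) -> tuple[bool, list[str]]:
    """Check a gene's taxon set against the eligibility rule.

    ``clade_definitions`` maps branch names to the full taxon sets of
    their focal clades.  Branches named in the rule's exemption list
    (single-taxon lineages such as a lone vampire-bat tip) need only
    one descendant present; all others need at least
    ``min_descendants_per_focal_clade``.
    """
    taxa = set(taxa)
    reasons = []
    if len(taxa) < rule.min_total_taxa:
        reasons.append(f"fewer than {rule.min_total_taxa} total taxa ({len(taxa)})")
    for branch, clade in clade_definitions.items():
        present = len(taxa & set(clade))
        required = (
            1
            if branch in rule.single_taxon_exempt_branches
            else rule.min_descendants_per_focal_clade
        )
        if present < required:
            reasons.append(
                f"branch {branch!r}: {present} descendant(s) present, {required} required"
            )
    return (not reasons), reasons


def trim_tree(reference_tree: LabeledTree, taxa) -> LabeledTree:
    """Restrict the reference phylogeny to a gene's taxon set.

    Leaves outside ``taxa`` are pruned; the resulting degree-2 nodes
    are collapsed with branch lengths summed (so pairwise path lengths
    between surviving leaves are preserved exactly), and the foreground
    bipartition is re-derived from the surviving taxa.  Raises
    :class:`ForegroundError` if either side of the foreground
    bipartition loses all of its taxa.
    """
    taxa = set(taxa)
    leaves = reference_tree.taxon_labels
    unknown = taxa - leaves
    if unknown:
        raise ValueError(f"taxa absent from reference tree: {sorted(unknown)}")
    fg = reference_tree.foreground
    new_fg = None
    if fg is not None:
        side_a = fg & taxa
        side_b = (leaves - fg) & taxa
        if not side_a or not side_b:
            raise ForegroundError(
                "foreground branch unidentifiable after trimming: one side of the "
                "bipartition has no surviving taxa"
            )
        new_fg = frozenset(side_a)
    tree = reference_tree.tree.clone(depth=1)
    tree.retain_taxa_with_labels(sorted(taxa))
    tree.purge_taxon_namespace()
    return LabeledTree(tree=tree, foreground=new_fg)
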