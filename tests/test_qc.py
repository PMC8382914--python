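import itertools

import dendropy
import numpy as np
import pytest

from branchsight.alignment import CodonAlignment
from branchsight.qc import (
    EligibilityRule,
    HitRecord,
    check_eligibility,
    mask_alignment,
    reciprocal_best_hits,
    select_representative,
    trim_tree,
)
from branchsight.trees import ForegroundError, LabeledTree


# ---------------------------------------------------------------- RBH

def test_rbh_empty_inputs():
    assert reciprocal_best_hits([], []) == []


def test_rbh_requires_reciprocity():
    fwd = [HitRecord("q1", "s1", 1e-10)]
    rev = [HitRecord("s1", "q2", 1e-10)]
    assert reciprocal_best_hits(fwd, rev) == []
    rev_ok = [HitRecord("s1", "q1", 1e-12)]
    assert reciprocal_best_hits(fwd, rev_ok) == [("q1", "s1")]


def test_rbh_evalue_threshold():
    fwd = [HitRecord("q1", "s1", 1e-5)]
    rev = [HitRecord("s1", "q1", 1e-12)]
    assert reciprocal_best_hits(fwd, rev, evalue_max=1e-6) == []


def test_rbh_symmetric_under_direction_swap():
    rng = np.random.default_rng(0)
    fwd, rev = [], []
    for i in range(20):
        fwd.append(HitRecord(f"q{i}", f"s{i % 7}", float(rng.uniform(1e-20, 1e-4))))
        rev.append(HitRecord(f"s{i % 7}", f"q{i % 5}", float(rng.uniform(1e-20, 1e-4))))
    a = set(reciprocal_best_hits(fwd, rev))
    b = {(q, s) for s, q in reciprocal_best_hits(rev, fwd)}
    assert a == b


def test_rbh_conflicting_ties_raise():
    fwd = [HitRecord("q1", "s1", 1e-10), HitRecord("q1", "s2", 1e-10)]
    with pytest.raises(ValueError, match="conflicting"):
        reciprocal_best_hits(fwd, [])


# ------------------------------------------------- representative choice

def test_representative_selection():
    assert select_representative(["ATG---"]) == "ATG---"
    seqs = ["A" * 8 + "-" * 12, "AAA" + "-" * 3 + "A" * 14, "A" * 13 + "-" * 7]
    assert select_representative(seqs) == seqs[1]  # 3 gaps beats 12 and 7
    tied = ["AT-", "A-T"]
    seq, sid = select_representative(tied, ids=["first", "second"])
    assert sid == "first"
    with pytest.raises(ValueError):
        select_representative([])


# ---------------------------------------------------------------- masking

def seq_aln(pairs):
    return CodonAlignment.from_sequences([p[0] for p in pairs], [p[1] for p in pairs])


def test_mask_noop_for_clean_alignment():
    aln = seq_aln([("Homo_sapiens", "ATGAAACCC"), ("bat1", "ATGAAACCA")])
    masked, report = mask_alignment(aln)
    assert np.array_equal(masked.states, aln.states)
    assert report.to_frame().empty


def test_mask_drops_reference_gap_columns():
    aln = seq_aln(
        [
            ("Homo_sapiens", "ATG---AAA---CCC"),
            ("bat1", "ATGTTTAAAGGGCCC"),
            ("bat2", "ATGTTTAAAGGGCCA"),
        ]
    )
    masked, report = mask_alignment(aln)
    assert masked.n_codons == 3
    assert report.removed_columns == (1, 3)
    assert masked.sequence_strings()[1] == "ATGAAACCC"


def test_mask_drops_gappy_sequences_after_column_removal():
    """Sequence gap fractions are measured on the surviving columns: a
    sequence gapped only where the reference is gapped survives."""
    aln = seq_aln(
        [
            ("Homo_sapiens", "ATG---AAACCC"),
            ("gap_only_in_ref_cols", "ATG---AAACCC"),
            ("too_gappy", "ATG------CCC"),
        ]
    )
    masked, report = mask_alignment(aln, seq_gap_max=0.5)
    assert "gap_only_in_ref_cols" in masked.taxon_ids
    # after dropping the reference-gap column, too_gappy is 1/3 gapped
    assert "too_gappy" in masked.taxon_ids
    aln2 = seq_aln(
        [
            ("Homo_sapiens", "ATGAAACCC"),
            ("bad", "---------"),
            ("ok", "ATGAAACCA"),
        ]
    )
    masked2, report2 = mask_alignment(aln2)
    assert report2.removed_sequences == ("bad",)
    assert masked2.taxon_ids == ("Homo_sapiens", "ok")


def test_mask_converts_majority_missing_columns():
    aln = seq_aln(
        [
            ("Homo_sapiens", "ATGAAA"),
            ("bat1", "ATGNNN"),
            ("bat2", "ATGNNN"),
        ]
    )
    masked, report = mask_alignment(aln, col_missing_max=0.5)
    assert report.masked_columns == (1,)
    assert (masked.states[:, 1] == -1).all()
    assert (masked.states[:, 0] >= 0).all()


def test_mask_requires_reference():
    aln = seq_aln([("bat1", "ATGAAA"), ("bat2", "ATGAAA")])
    with pytest.raises(ValueError, match="reference"):
        mask_alignment(aln)


# ------------------------------------------------------------ eligibility

def test_eligibility_minimum_taxa():
    ok, reasons = check_eligibility([f"t{i}" for i in range(9)], {})
    assert not ok
    assert "fewer than 10" in reasons[0]
    ok, reasons = check_eligibility([f"t{i}" for i in range(10)], {})
    assert ok


def test_eligibility_clade_descendants():
    taxa = [f"t{i}" for i in range(12)]
    clades = {"focal": {"t0", "x1", "x2"}}  # only t0 present
    ok, reasons = check_eligibility(taxa, clades)
    assert not ok
    assert "1 descendant" in reasons[0]
    # a single-taxon lineage on the exemption list needs just one
    rule = EligibilityRule(single_taxon_exempt_branches=frozenset({"focal"}))
    ok, _ = check_eligibility(taxa, clades, rule)
    assert ok


# ------------------------------------------------------------- tree trim

def tree6(fg=None):
    newick = "((A:0.1,B:0.2):0.05,(C:0.1,(D:0.2,E:0.1):0.3):0.07,F:0.4);"
    return LabeledTree(
        tree=dendropy.Tree.get(data=newick, schema="newick"),
        foreground=frozenset(fg) if fg else None,
    )


def pairwise_paths(ltree, taxa):
    pdm = ltree.tree.phylogenetic_distance_matrix()
    ns = ltree.tree.taxon_namespace
    return {
        (a, b): pdm.distance(ns.get_taxon(a), ns.get_taxon(b))
        for a, b in itertools.combinations(sorted(taxa), 2)
    }


def test_trim_full_set_is_identity():
    t = tree6(fg={"D", "E"})
    trimmed = trim_tree(t, t.taxon_labels)
    assert trimmed.taxon_labels == t.taxon_labels
    assert pairwise_paths(trimmed, t.taxon_labels) == pytest.approx(
        pairwise_paths(t, t.taxon_labels)
    )


def test_trim_preserves_foreground_and_path_lengths():
    t = tree6(fg={"D", "E"})
    keep = {"A", "C", "D", "E", "F"}
    trimmed = trim_tree(t, keep)
    assert trimmed.foreground == frozenset({"D", "E"})
    assert trimmed.foreground_edge() is not None
    assert pairwise_paths(trimmed, keep) == pytest.approx(pairwise_paths(t, keep))


def test_trim_to_single_foreground_survivor():
    t = tree6(fg={"D", "E"})
    trimmed = trim_tree(t, {"A", "B", "C", "D"})
    assert trimmed.foreground == frozenset({"D"})
    edge = trimmed.foreground_edge()
    assert trimmed.leaf_set(edge) == frozenset({"D"})


def test_trim_unidentifiable_foreground_raises():
    t = tree6(fg={"D", "E"})
    with pytest.raises(ForegroundError):
        trim_tree(t, {"A", "B", "C"})  # foreground side entirely lost


def test_trim_unknown_taxa_rejected():
    t = tree6()
    with pytest.raises(ValueError, match="absent"):
        trim_tree(t, {"A", "Z"})
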