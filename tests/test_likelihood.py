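import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

from branchsight.alignment import CodonAlignment
from branchsight.likelihood import (
    LikelihoodEngine,
    M0Spec,
    ModelAParams,
    ModelASpec,
)
from branchsight.matrices import uniform_codon_freqs
from branchsight.trees import LabeledTree

from _oracles import naive_q, star_tree_mixture_loglik


def star_tree(lengths, fg=None):
    taxa = [f"t{i}" for i in range(len(lengths))]
    parts = ",".join(f"{t}:{l}" for t, l in zip(taxa, lengths))
    return LabeledTree(
        tree=dendropy.Tree.get(data=f"({parts});", schema="newick"),
        foreground=frozenset(fg) if fg else None,
    )


@pytest.mark.parametrize("n_taxa,n_codons,seed", [(2, 5, 0), (3, 10, 1), (3, 6, 2)])
def test_m0_matches_exhaustive_enumeration(n_taxa, n_codons, seed):
    """Pruning equals brute-force summation over root states."""
    rng = np.random.default_rng(seed)
    lengths = rng.uniform(0.05, 0.6, size=n_taxa)
    tree = star_tree(lengths)
    states = rng.integers(0, 61, size=(n_taxa, n_codons))
    states[0, 0] = -1  # one ambiguous codon exercises the gap path
    aln = CodonAlignment(taxon_ids=tuple(f"t{i}" for i in range(n_taxa)), states=states)
    pi = uniform_codon_freqs()
    engine = LikelihoodEngine(aln, tree, codon_freqs=pi)
    got = engine.log_likelihood(M0Spec(kappa=2.3, omega=0.4))
    want = star_tree_mixture_loglik(
        states, lengths, np.zeros(n_taxa, dtype=bool), [(1.0, 0.4, 0.4)], 2.3, pi
    )
    assert got == pytest.approx(want, abs=1e-8)


def test_model_a_matches_exhaustive_enumeration():
    """Four-class mixture with a pendant foreground branch against the
    independent enumeration oracle."""
    rng = np.random.default_rng(5)
    lengths = np.array([0.3, 0.15, 0.4])
    tree = star_tree(lengths, fg={"t0"})
    states = rng.integers(0, 61, size=(3, 10))
    aln = CodonAlignment(taxon_ids=("t0", "t1", "t2"), states=states)
    pi = uniform_codon_freqs()
    params = ModelAParams(p0=0.5, p1=0.3, omega0=0.2, omega2=3.0, kappa=1.8)
    engine = LikelihoodEngine(aln, tree, codon_freqs=pi)
    got = engine.log_likelihood(ModelASpec(params))
    classes = [
        (params.p0, 0.2, 0.2),
        (params.p1, 1.0, 1.0),
        (params.p2a, 0.2, 3.0),
        (params.p2b, 1.0, 3.0),
    ]
    want = star_tree_mixture_loglik(
        states, lengths, np.array([True, False, False]), classes, 1.8, pi
    )
    assert got == pytest.approx(want, abs=1e-8)


def test_alternative_at_boundary_equals_null(benchmark_tree, random_alignment):
    """Model A with omega2 = 1 is exactly the null model."""
    aln = random_alignment(n_taxa=8, n_codons=20, seed=4, taxa=sorted(benchmark_tree.taxon_labels))
    engine = LikelihoodEngine(aln, benchmark_tree)
    alt = ModelAParams(p0=0.6, p1=0.2, omega0=0.1, omega2=1.0, kappa=2.0, null=False)
    null = ModelAParams(p0=0.6, p1=0.2, omega0=0.1, omega2=1.0, kappa=2.0, null=True)
    l_alt = engine.log_likelihood(ModelASpec(alt))
    l_null = engine.log_likelihood(ModelASpec(null))
    assert l_alt == pytest.approx(l_null, abs=1e-10)


def test_duplicated_site_adds_its_own_loglik(benchmark_tree, random_alignment):
    """Sites are independent: duplicating one adds exactly its lnL."""
    taxa = sorted(benchmark_tree.taxon_labels)
    aln = random_alignment(n_taxa=8, n_codons=6, seed=9, taxa=taxa)
    pi = uniform_codon_freqs()
    spec = M0Spec(kappa=2.0, omega=0.3)
    base = LikelihoodEngine(aln, benchmark_tree, codon_freqs=pi).log_likelihood(spec)
    single = CodonAlignment(taxon_ids=aln.taxon_ids, states=aln.states[:, [2]])
    one = LikelihoodEngine(single, benchmark_tree, codon_freqs=pi).log_likelihood(spec)
    dup = CodonAlignment(
        taxon_ids=aln.taxon_ids,
        states=np.concatenate([aln.states, aln.states[:, [2]]], axis=1),
    )
    both = LikelihoodEngine(dup, benchmark_tree, codon_freqs=pi).log_likelihood(spec)
    assert both == pytest.approx(base + one, abs=1e-8)


def test_m0_invariant_to_taxon_and_site_order(benchmark_tree, random_alignment):
    taxa = sorted(benchmark_tree.taxon_labels)
    aln = random_alignment(n_taxa=8, n_codons=15, seed=2, taxa=taxa)
    pi = uniform_codon_freqs()
    spec = M0Spec(kappa=1.7, omega=0.6)
    base = LikelihoodEngine(aln, benchmark_tree, codon_freqs=pi).log_likelihood(spec)
    perm = np.random.default_rng(0).permutation(len(taxa))
    shuffled = CodonAlignment(
        taxon_ids=tuple(taxa[i] for i in perm), states=aln.states[perm]
    )
    assert LikelihoodEngine(shuffled, benchmark_tree, codon_freqs=pi).log_likelihood(
        spec
    ) == pytest.approx(base, abs=1e-8)
    site_perm = np.random.default_rng(1).permutation(aln.n_codons)
    reordered = CodonAlignment(taxon_ids=aln.taxon_ids, states=aln.states[:, site_perm])
    assert LikelihoodEngine(reordered, benchmark_tree, codon_freqs=pi).log_likelihood(
        spec
    ) == pytest.approx(base, abs=1e-8)


def test_all_gap_column_contributes_nothing(benchmark_tree, random_alignment):
    taxa = sorted(benchmark_tree.taxon_labels)
    aln = random_alignment(n_taxa=8, n_codons=5, seed=6, taxa=taxa)
    pi = uniform_codon_freqs()
    spec = M0Spec(kappa=2.0, omega=0.5)
    base = LikelihoodEngine(aln, benchmark_tree, codon_freqs=pi).log_likelihood(spec)
    gap_col = np.full((8, 1), -1)
    padded = CodonAlignment(
        taxon_ids=aln.taxon_ids, states=np.concatenate([aln.states, gap_col], axis=1)
    )
    assert LikelihoodEngine(padded, benchmark_tree, codon_freqs=pi).log_likelihood(
        spec
    ) == pytest.approx(base, abs=1e-8)


def test_model_a_requires_foreground(random_alignment):
    tree = star_tree([0.1, 0.2, 0.3])
    aln = random_alignment(n_taxa=3, n_codons=4, seed=0, taxa=["t0", "t1", "t2"])
    params = ModelAParams(p0=0.5, p1=0.3, omega0=0.2, omega2=2.0, kappa=2.0)
    with pytest.raises(ValueError, match="foreground"):
        LikelihoodEngine(aln, tree).log_likelihood(ModelASpec(params))


def test_m0_length_gradient_matches_finite_differences(benchmark_tree, random_alignment):
    taxa = sorted(benchmark_tree.taxon_labels)
    aln = random_alignment(n_taxa=8, n_codons=30, seed=12, taxa=taxa)
    engine = LikelihoodEngine(aln, benchmark_tree)
    lengths = engine.arrays.branch_lengths.copy()
    lnL, grad = engine.m0_loglik_and_length_grad(2.0, 0.3, lengths)
    h = 1e-6
    for k in range(len(lengths)):
        lp, lm = lengths.copy(), lengths.copy()
        lp[k] += h
        lm[k] -= h
        fd = (
            engine.m0_loglik_and_length_grad(2.0, 0.3, lp)[0]
            - engine.m0_loglik_and_length_grad(2.0, 0.3, lm)[0]
        ) / (2 * h)
        assert grad[k] == pytest.approx(fd, abs=1e-4, rel=1e-4)
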