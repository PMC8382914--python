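import dendropy
import numpy as np
import pytest

from branchsight.alignment import CodonAlignment
from branchsight.matrices import uniform_codon_freqs
from branchsight.simulate import default_benchmark_tree, simulate_alignment, spec_for_regime
from branchsight.trees import LabeledTree


@pytest.fixture(scope="session")
def uniform_pi():
    return uniform_codon_freqs()


@pytest.fixture()
def benchmark_tree():
    return default_benchmark_tree()


@pytest.fixture(scope="session")
def six_taxon_tree():
    newick = "((A:0.12,B:0.08):0.06,(C:0.1,D:0.15):0.09,(E:0.2,F:0.11):0.07);"
    return LabeledTree(
        tree=dendropy.Tree.get(data=newick, schema="newick"),
        foreground=frozenset({"A", "B"}),
    )


@pytest.fixture()
def random_alignment():
    """Factory for small random codon alignments (valid sense states)."""

    def make(n_taxa=3, n_codons=8, seed=0, taxa=None):
        rng = np.random.default_rng(seed)
        taxa = taxa or tuple(f"t{i}" for i in range(n_taxa))
        states = rng.integers(0, 61, size=(len(taxa), n_codons))
        return CodonAlignment(taxon_ids=tuple(taxa), states=states)

    return make


@pytest.fixture(scope="session")
def small_fitted_gene():
    """One 150-codon correct-null gene fitted once for reuse."""
    from branchsight.fit import FitSettings, fit_branch_site

    tree = default_benchmark_tree()
    spec = spec_for_regime("correct-null", n_codons=150, seed=11)
    aln, labels = simulate_alignment(spec)
    fit_null, fit_alt, lrt = fit_branch_site(
        aln, tree, FitSettings(n_starts=0, seed=0, branch_mode="m0")
    )
    return {
        "tree": tree,
        "alignment": aln,
        "labels": labels,
        "null": fit_null,
        "alt": fit_alt,
        "lrt": lrt,
    }
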