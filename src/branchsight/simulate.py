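"""Synthetic codon alignments evolved under M0/Model A regimes.

The generator exists to exercise the branch-site test under the three
conditions that matter for its null distribution:

* ``correct-null`` — data generated under the null branch-site model
  itself (a purifying class, a neutral class, and foreground classes
  with omega2 = 1), for which the LRT statistic should follow the
  boundary-condition 50:50 mixture of a point mass at zero and
  chi-square(1);
* ``conserved-only`` — every site purifying (omega well below 1) and no
  neutral class, the misspecified situation typical of real conserved
  proteins, which pushes the true parameter deep into the forbidden
  zone and inflates the share of zero statistics (p = 1);
* ``positive`` — a fraction of sites with omega2 > 1 on the foreground
  branch, supplying true positives for power and recovery checks.

Each site keeps one class across the whole tree; classes 2a/2b switch
omega only on the foreground edge, matching Model A's generative
assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import CodonAlignment, write_codon_fasta
from .matrices import build_q_matrix, transition_matrix, uniform_codon_freqs
from .trees import LabeledTree

__all__ = [
    "SiteClass",
    "SimulationSpec",
    "simulate_alignment",
    "make_benchmark",
    "default_benchmark_tree",
    "REGIMES",
]

#: Default benchmark phylogeny: 8 leaves, internal foreground branch
#: (the stem of clade {A, B, C, D}), branch lengths 0.05-0.3.
DEFAULT_TREE_NEWICK = (
    "(((A:0.10,B:0.12):0.08,(C:0.09,D:0.11):0.07):0.15 #1,"
    "(E:0.10,F:0.13):0.09,(G:0.20,H:0.18):0.05);"
)


def default_benchmark_tree() -> LabeledTree:
    from .trees import _parse_newick, parse_newick_foreground

    cleaned, fg = parse_newick_foreground(DEFAULT_TREE_NEWICK)
    return LabeledTree(tree=_parse_newick(cleaned), foreground=fg)


@dataclass(frozen=True)
class SiteClass:
    """One mixture component: proportion and background/foreground omega."""

    proportion: float
    omega_background: float
    omega_foreground: float
    label: str


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one simulated gene."""

    tree: LabeledTree
    n_codons: int
    site_classes: tuple[SiteClass, ...]
    kappa: float = 2.0
    codon_freqs: np.ndarray = field(default_factory=uniform_codon_freqs)
    seed: int | None = None
    regime: str = "custom"

    def __post_init__(self):
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        total = sum(c.proportion for c in self.site_classes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"site-class proportions must sum to 1 (got {total})")
        uses_fg = any(
            c.omega_background != c.omega_foreground for c in self.site_classes
        )
        if uses_fg and self.tree.foreground is None:
            raise ValueError("foreground omega switch requires a labeled tree")


def _regime_classes(regime: str, **kw) -> tuple[SiteClass, ...]:
    if regime == "correct-null":
        # Data drawn from the null branch-site model itself: the
        # foreground classes exist but sit exactly at omega2 = 1.
        p0, p1, w0 = kw.get("p0", 0.55), kw.get("p1", 0.30), kw.get("omega0", 0.1)
        p2 = 1.0 - p0 - p1
        return (
            SiteClass(p0, w0, w0, "0"),
            SiteClass(p1, 1.0, 1.0, "1"),
            SiteClass(p2 * p0 / (p0 + p1), w0, 1.0, "2a"),
            SiteClass(p2 * p1 / (p0 + p1), 1.0, 1.0, "2b"),
        )
    if regime == "conserved-only":
        # No neutral class anywhere: all sites purifying, the paper's
        # misspecification mechanism ("deep inside the forbidden zone").
        return (
            SiteClass(kw.get("p_strong", 0.7), 0.05, 0.05, "w0.05"),
            SiteClass(1.0 - kw.get("p_strong", 0.7), 0.3, 0.3, "w0.3"),
        )
    if regime == "positive":
        p0, p1, w0 = kw.get("p0", 0.55), kw.get("p1", 0.30), kw.get("omega0", 0.1)
        w2 = kw.get("omega2", 4.0)
        p2 = 1.0 - p0 - p1  # 15% of sites under foreground selection
        return (
            SiteClass(p0, w0, w0, "0"),
            SiteClass(p1, 1.0, 1.0, "1"),
            SiteClass(p2 * p0 / (p0 + p1), w0, w2, "2a"),
            SiteClass(p2 * p1 / (p0 + p1), 1.0, w2, "2b"),
        )
    raise ValueError(f"unknown regime {regime!r}")


REGIMES = ("correct-null", "conserved-only", "positive")


def spec_for_regime(
    regime: str,
    tree: LabeledTree | None = None,
    n_codons: int = 300,
    kappa: float = 2.0,
    seed: int | None = None,
    **kw,
) -> SimulationSpec:
    """Standard SimulationSpec for one of the three study regimes."""
    return SimulationSpec(
        tree=tree if tree is not None else default_benchmark_tree(),
        n_codons=n_codons,
        site_classes=_regime_classes(regime, **kw),
        kappa=kappa,
        seed=seed,
        regime=regime,
    )


def simulate_alignment(spec: SimulationSpec) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve one codon alignment along the labeled tree.

    Returns the alignment and the per-site truth labels (class labels
    from the spec).  Root codons are drawn from the equilibrium
    frequencies; each edge applies the class-appropriate transition
    matrix.  Reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    arrays = spec.tree.pruning_arrays(
        sorted(spec.tree.taxon_labels)
    )
    taxa = sorted(spec.tree.taxon_labels)

    props = np.array([c.proportion for c in spec.site_classes])
    class_of_site = rng.choice(len(props), size=spec.n_codons, p=props)
    labels = np.array([spec.site_classes[k].label for k in class_of_site])

    omegas = sorted(
        {c.omega_background for c in spec.site_classes}
        | {c.omega_foreground for c in spec.site_classes}
    )
    models = {w: build_q_matrix(spec.kappa, w, spec.codon_freqs) for w in omegas}
    # branch lengths are expected substitutions per codon averaged over
    # the site-class mixture — the same convention the likelihood uses
    r_bg = sum(c.proportion * models[c.omega_background].prescale_rate for c in spec.site_classes)
    r_fg = sum(c.proportion * models[c.omega_foreground].prescale_rate for c in spec.site_classes)

    states = np.empty((arrays.n_nodes, spec.n_codons), dtype=np.int64)
    states[arrays.root_index] = rng.choice(
        len(spec.codon_freqs), size=spec.n_codons, p=spec.codon_freqs
    )
    # walk edges root-to-tip (reverse postorder)
    for k in reversed(range(arrays.n_edges)):
        child = arrays.child_index[k]
        parent = arrays.parent_index[k]
        t = arrays.branch_lengths[k]
        for ci, sclass in enumerate(spec.site_classes):
            sites = np.where(class_of_site == ci)[0]
            if sites.size == 0:
                continue
            if arrays.is_foreground[k]:
                w, scale = sclass.omega_foreground, r_fg
            else:
                w, scale = sclass.omega_background, r_bg
            P = transition_matrix(models[w], t * models[w].prescale_rate / scale)
            cum = np.cumsum(P, axis=1)
            u = rng.random(sites.size)
            parent_states = states[parent, sites]
            states[child, sites] = np.argmax(
                u[:, None] < cum[parent_states], axis=1
            )
    aln = CodonAlignment(
        taxon_ids=tuple(taxa), states=states[: arrays.n_leaves].copy()
    )
    return aln, labels


@dataclass(frozen=True)
class BenchmarkGene:
    gene_id: str
    regime: str
    seed: int
    alignment: CodonAlignment
    tree: LabeledTree
    truth_labels: np.ndarray


def make_benchmark(
    n_genes_per_regime: int,
    seed: int = 0,
    regimes=REGIMES,
    tree: LabeledTree | None = None,
    n_codons: int = 300,
    out_dir: str | Path | None = None,
) -> tuple[list[BenchmarkGene], pd.DataFrame]:
    """Simulate a labeled cohort covering the requested regimes.

    Returns the genes and a manifest table (gene id, regime, seed,
    codon count).  If ``out_dir`` is given, writes one FASTA per gene,
    the shared Newick tree, and ``manifest.tsv``.
    """
    if n_genes_per_regime < 1:
        raise ValueError("n_genes_per_regime must be >= 1")
    tree = tree if tree is not None else default_benchmark_tree()
    child_seeds = np.random.SeedSequence(seed).generate_state(
        n_genes_per_regime * len(regimes)
    ) % (2**31)
    genes: list[BenchmarkGene] = []
    rows = []
    i = 0
    for regime in regimes:
        for rep in range(n_genes_per_regime):
            gseed = int(child_seeds[i])
            i += 1
            spec = spec_for_regime(regime, tree=tree, n_codons=n_codons, seed=gseed)
            aln, labels = simulate_alignment(spec)
            gene_id = f"{regime}_{rep:03d}"
            genes.append(
                BenchmarkGene(
                    gene_id=gene_id,
                    regime=regime,
                    seed=gseed,
                    alignment=aln,
                    tree=tree,
                    truth_labels=labels,
                )
            )
            rows.append(
                {
                    "gene_id": gene_id,
                    "regime": regime,
                    "seed": gseed,
                    "n_codons": n_codons,
                    "n_taxa": aln.n_taxa,
                }
            )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for g in genes:
            write_codon_fasta(g.alignment, out_dir / f"{g.gene_id}.fasta")
        (out_dir / "tree.nwk").write_text(tree.to_newick() + "\n")
        manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return genes, manifest
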